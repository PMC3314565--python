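"""Synthetic exon-array case studies with known ground truth.

The generator emulates the post-summarization output of an exon-array
experiment on paired normal/pathological tissue: a probeset x sample
matrix of log2 intensities in which

``x[ps, s] = mu_g + a_ps + c_g * 1(s pathological)
            + delta * d_ps * 1(s pathological, ps spliced)
            + covariate effects + eps``,

with gene baseline ``mu_g ~ Normal(baseline_mean, baseline_sd^2)``,
probeset affinity ``a_ps ~ Normal(0, 1)`` shared across samples
(emulating RMA's probe-affinity structure without implementing RMA),
gene-level disease shift ``c_g``, exon-level splicing effect ``delta``
and i.i.d. noise ``eps ~ Normal(0, noise_sd^2)``.

Splicing events come in two modes.  ``cassette``: one probeset of the
gene loses ``delta`` log2 units in the pathological group (the exon is
skipped in disease, so the normal signal is higher).  ``mutually_
exclusive``: one probeset gains ``delta`` in disease while an
adjacent-exon probeset loses ``delta`` — the opposed-peaks pattern that
a mutually exclusive exon pair produces.  Isoform annotation is written
consistently: the two exons of a mutually exclusive pair never co-occur
in an isoform.

Clinical covariates (gender, age of onset, optionally stage) are drawn
per patient, independently of condition.  A covariate effect adds a
constant to a chosen set of probesets for the samples matching the
covariate rule (categorical level, or numeric value above a threshold),
planting splicing patterns that correlate with clinical variables
rather than with disease status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import Dataset, NORMAL, PATHOLOGICAL

__all__ = ["CovariateEffect", "SimulationConfig", "TruthTable", "simulate_dataset"]


@dataclass(frozen=True)
class CovariateEffect:
    """A planted covariate-linked expression effect.

    For a ``numeric`` covariate the effect is added to the affected
    probesets in every sample whose covariate value is strictly above
    ``threshold``; for a ``categorical`` covariate, in every sample whose
    value equals ``levels[0]``.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    effect: float
    n_affected: int
    threshold: float | None = None
    levels: tuple[str, ...] = ("M", "F")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model; defaults mirror a small
    paired cancer case study (14 patients, one normal and one tumor
    specimen each)."""

    n_genes: int = 100
    probesets_per_gene: tuple[int, int] = (5, 12)
    n_pairs: int = 14
    gene_de_fraction: float = 0.1
    gene_de_effect: float = 1.0
    as_fraction: float = 0.1
    as_effect: float = 1.0
    as_mode: str = "cassette"  # "cassette" | "mutually_exclusive"
    covariates: tuple[CovariateEffect, ...] = ()
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    background_fraction: float = 0.1
    paired: bool = True
    include_gender: bool = True
    include_age: bool = True
    include_stage: bool = False
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("gene_de_fraction", "as_fraction", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        kmin, kmax = self.probesets_per_gene
        if kmin < 1 or kmax < kmin:
            raise ValueError("probesets_per_gene must satisfy 1 <= min <= max")
        if self.as_mode not in ("cassette", "mutually_exclusive"):
            raise ValueError(f"unknown as_mode {self.as_mode!r}")
        if self.as_fraction > 0 and self.as_mode == "mutually_exclusive" and kmax < 2:
            raise ValueError(
                "mutually_exclusive events need probesets_per_gene max >= 2"
            )
        for cov in self.covariates:
            if cov.kind not in ("numeric", "categorical"):
                raise ValueError(f"covariate {cov.name}: unknown kind {cov.kind!r}")
            if cov.kind == "numeric" and cov.threshold is None:
                raise ValueError(f"numeric covariate {cov.name} needs a threshold")
        return self


@dataclass
class TruthTable:
    """Ground truth of a simulated case study.

    ``probesets``: per-probeset flags — ``is_as`` and ``as_direction``
    (+1 when the normal signal is higher, i.e. expected positive
    splicing index; -1 for the converse; 0 for unaffected probesets) and
    ``is_background``.  ``genes``: per-gene ``is_as``, ``is_de``,
    ``de_direction`` (+1 = higher in pathological).  ``covariates``: one
    row per planted covariate effect with the affected probeset ids and
    the true threshold.
    """

    probesets: pd.DataFrame
    genes: pd.DataFrame
    covariates: pd.DataFrame


# log2 offset of unexpressed (background) probesets below the gene baseline
_BACKGROUND_OFFSET = 4.0
# DABG p-values: expressed ~ U(0, this); background ~ U(0, 1)
_DABG_EXPRESSED_MAX = 0.01


def _exact_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, TruthTable]:
    """Draw one case study from the generative model.

    Identical configs (including ``seed``) produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    kmin, kmax = config.probesets_per_gene

    # --- gene / probeset scaffold -------------------------------------
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    k_per_gene = rng.integers(kmin, kmax + 1, size=config.n_genes)
    chroms = [f"chr{(i % 22) + 1}" for i in range(config.n_genes)]
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    ann_rows = []
    chrom_cursor: dict[str, int] = {}
    ps_counter = 0
    gene_of_ps: list[int] = []
    for gi, gene in enumerate(gene_ids):
        k = int(k_per_gene[gi])
        pos = chrom_cursor.get(chroms[gi], 1)
        for ei in range(k):
            ps_counter += 1
            start = pos + ei * 500
            # exon_index counts in transcription order: genomic order on
            # the plus strand, reversed on the minus strand
            exon_index = ei + 1 if strands[gi] == "+" else k - ei
            ann_rows.append(
                {
                    "probeset_id": f"PS{ps_counter:06d}",
                    "transcript_cluster_id": f"TC{gi + 1:04d}",
                    "gene_id": gene,
                    "chrom": chroms[gi],
                    "start": start,
                    "stop": start + 149,
                    "strand": str(strands[gi]),
                    "exon_index": exon_index,
                }
            )
            gene_of_ps.append(gi)
        chrom_cursor[chroms[gi]] = pos + k * 500 + 5000
    ann = pd.DataFrame(ann_rows).set_index("probeset_id")
    n_ps = len(ann)
    gene_of_ps = np.asarray(gene_of_ps)

    # --- planted events ----------------------------------------------
    n_as = _exact_count(config.as_fraction, config.n_genes)
    eligible = np.flatnonzero(k_per_gene >= 2) if n_as else np.array([], dtype=int)
    if n_as > len(eligible):
        raise ValueError(
            "not enough genes with >= 2 probesets to plant the requested AS events"
        )
    as_genes = np.sort(rng.choice(eligible, size=n_as, replace=False)) if n_as else eligible
    as_gene_set = set(as_genes.tolist())

    # as_direction: expected sign of the splicing index (normal - pathological)
    ps_as_dir = np.zeros(n_ps)
    ps_index_by_gene = {gi: np.flatnonzero(gene_of_ps == gi) for gi in as_gene_set}
    for gi in as_genes:
        members = ps_index_by_gene[int(gi)]
        k = len(members)
        if config.as_mode == "cassette":
            j = int(rng.integers(0, k))
            ps_as_dir[members[j]] = +1.0  # exon lost in disease -> SI > 0
        else:
            j = int(rng.integers(0, k - 1))
            ps_as_dir[members[j]] = -1.0  # exon gained in disease -> SI < 0
            ps_as_dir[members[j + 1]] = +1.0

    n_de = _exact_count(config.gene_de_fraction, config.n_genes)
    de_genes = np.sort(rng.choice(config.n_genes, size=n_de, replace=False)) if n_de else []
    de_dir = np.zeros(config.n_genes)
    if n_de:
        de_dir[de_genes] = np.where(rng.random(n_de) < 0.5, -1.0, 1.0)

    n_bg = _exact_count(config.background_fraction, n_ps)
    bg_candidates = np.flatnonzero(ps_as_dir == 0)
    if n_bg > len(bg_candidates):
        n_bg = len(bg_candidates)
    is_bg = np.zeros(n_ps, dtype=bool)
    if n_bg:
        is_bg[np.sort(rng.choice(bg_candidates, size=n_bg, replace=False))] = True

    # --- samples and clinical covariates ------------------------------
    n_patients = config.n_pairs if config.paired else 2 * config.n_pairs
    patients = [f"PT{i + 1:03d}" for i in range(n_patients)]
    gender = rng.choice(["M", "F"], size=n_patients)
    age = rng.integers(40, 81, size=n_patients)
    stage = rng.choice(["I", "II", "III"], size=n_patients)

    sample_rows = []
    for pi, pt in enumerate(patients):
        if config.paired:
            conds = [(f"{pt}_N", NORMAL), (f"{pt}_T", PATHOLOGICAL)]
        else:
            cond = NORMAL if pi < config.n_pairs else PATHOLOGICAL
            conds = [(f"{pt}_{'N' if cond == NORMAL else 'T'}", cond)]
        for sid, cond in conds:
            row = {"sample_id": sid, "condition": cond, "patient_id": pt}
            if config.include_gender:
                row["gender"] = gender[pi]
            if config.include_age:
                row["age"] = int(age[pi])
            if config.include_stage:
                row["stage"] = stage[pi]
            sample_rows.append(row)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(samples)
    is_path = (samples["condition"] == PATHOLOGICAL).to_numpy()

    kinds: dict[str, str] = {}
    if config.include_gender:
        kinds["gender"] = "categorical"
    if config.include_age:
        kinds["age"] = "numeric"
    if config.include_stage:
        kinds["stage"] = "categorical"

    # --- expression matrix -------------------------------------------
    mu_g = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    a_ps = rng.normal(0.0, 1.0, size=n_ps)
    noise = rng.normal(0.0, config.noise_sd, size=(n_ps, n_samples)) if config.noise_sd > 0 else np.zeros((n_ps, n_samples))

    x = mu_g[gene_of_ps, None] + a_ps[:, None] + noise
    # gene-level disease shift
    c = config.gene_de_effect * de_dir[gene_of_ps]
    x += c[:, None] * is_path[None, :]
    # exon-level splicing effect: direction is the SI sign, i.e. the
    # pathological group moves by -direction * delta
    x += (-ps_as_dir * config.as_effect)[:, None] * is_path[None, :]
    # background probesets sit near the detection floor regardless
    bg_level = config.baseline_mean - _BACKGROUND_OFFSET
    x[is_bg, :] = bg_level + noise[is_bg, :]

    # covariate-linked effects
    cov_rows = []
    affected_pool = np.flatnonzero((ps_as_dir == 0) & ~is_bg)
    for cov in config.covariates:
        if cov.name not in samples.columns:
            raise ValueError(f"covariate effect {cov.name!r}: no such metadata column")
        kinds.setdefault(cov.name, cov.kind)
        if cov.n_affected > len(affected_pool):
            raise ValueError(f"covariate effect {cov.name!r}: not enough free probesets")
        chosen = np.sort(rng.choice(affected_pool, size=cov.n_affected, replace=False))
        affected_pool = np.setdiff1d(affected_pool, chosen)
        col = samples[cov.name]
        if cov.kind == "numeric":
            mask = pd.to_numeric(col).to_numpy() > cov.threshold
        else:
            mask = (col == cov.levels[0]).to_numpy()
        x[np.ix_(chosen, mask)] += cov.effect
        cov_rows.append(
            {
                "name": cov.name,
                "kind": cov.kind,
                "effect": cov.effect,
                "threshold": cov.threshold if cov.threshold is not None else np.nan,
                "affected_probesets": ";".join(ann.index[chosen]),
            }
        )

    expression = pd.DataFrame(x, index=ann.index, columns=samples.index)

    # --- DABG ---------------------------------------------------------
    dabg_vals = rng.uniform(0.0, 1.0, size=(n_ps, n_samples))
    dabg_vals[~is_bg, :] *= _DABG_EXPRESSED_MAX
    dabg = pd.DataFrame(dabg_vals, index=ann.index, columns=samples.index)

    # --- isoform annotation ------------------------------------------
    isoforms: list[frozenset[str]] = [frozenset()] * n_ps
    for gi, gene in enumerate(gene_ids):
        members = np.flatnonzero(gene_of_ps == gi)
        expressed = [m for m in members if not is_bg[m]]
        if not expressed:
            continue
        base = f"NM_{gene}"
        dirs = ps_as_dir[expressed]
        if gi in as_gene_set and config.as_mode == "cassette":
            skipped = [m for m, d in zip(expressed, dirs) if d > 0]
            for m in expressed:
                iso = {f"{base}.1"}
                if m not in skipped:
                    iso.add(f"{base}.2")  # isoform lacking the cassette exon
                isoforms[m] = frozenset(iso)
        elif gi in as_gene_set and config.as_mode == "mutually_exclusive":
            up = [m for m, d in zip(expressed, dirs) if d < 0]
            down = [m for m, d in zip(expressed, dirs) if d > 0]
            for m in expressed:
                iso = set()
                if m not in down:
                    iso.add(f"{base}.1")  # carries the disease-gained exon
                if m not in up:
                    iso.add(f"{base}.2")  # carries the disease-lost exon
                isoforms[m] = frozenset(iso)
        else:
            for m in expressed:
                isoforms[m] = frozenset({f"{base}.1"})
    ann["isoform_ids"] = isoforms

    gene_sets = pd.DataFrame(
        {
            "set_id": [f"PW{(gi % 10) + 1:02d}" for gi in range(config.n_genes)]
            + [f"GO:{7000 + (gi % 15):07d}" for gi in range(config.n_genes)],
            "gene_id": gene_ids * 2,
            "kind": ["pathway"] * config.n_genes + ["go"] * config.n_genes,
        }
    )

    from .io import _genes_from_annotation  # gene table derivation shared with load

    genes = _genes_from_annotation(ann, gene_sets)

    dataset = Dataset(
        expression=expression,
        samples=samples,
        probesets=ann,
        genes=genes,
        dabg=dabg,
        gene_sets=gene_sets,
        covariate_kinds=kinds,
    ).validate()

    truth = TruthTable(
        probesets=pd.DataFrame(
            {
                "gene_id": ann["gene_id"].to_numpy(),
                "is_as": ps_as_dir != 0,
                "as_direction": ps_as_dir.astype(int),
                "is_background": is_bg,
            },
            index=ann.index,
        ),
        genes=pd.DataFrame(
            {
                "is_as": [gi in as_gene_set for gi in range(config.n_genes)],
                "is_de": de_dir != 0,
                "de_direction": de_dir.astype(int),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        covariates=pd.DataFrame(
            cov_rows, columns=["name", "kind", "effect", "threshold", "affected_probesets"]
        ),
    )
    return dataset, truth


def write_simulation(dataset: Dataset, truth: TruthTable, outdir) -> dict[str, str]:
    """Write the four case-study files plus ground truth to ``outdir``."""
    import os

    from .io import write_table

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_table(dataset.expression, _p("expression.tsv"))
    write_table(dataset.dabg, _p("dabg.tsv"))
    meta = dataset.samples.copy()
    meta.to_csv(_p("metadata.csv"))
    ann = dataset.probesets.copy()
    ann["isoform_ids"] = ann["isoform_ids"].map(lambda s: ";".join(sorted(s)))
    ann.to_csv(_p("annotation.tsv"), sep="\t")
    dataset.gene_sets.to_csv(_p("gene_sets.tsv"), sep="\t", index=False)
    truth_table = truth.probesets.join(truth.genes, on="gene_id", rsuffix="_gene")
    write_table(truth_table, _p("truth.tsv"))
    if len(truth.covariates):
        truth.covariates.to_csv(_p("truth_covariates.tsv"), sep="\t", index=False)
    return paths
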