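"""Synthetic transcriptome generator for seed-mediated off-target analysis.

The generator emulates the statistical structure that the enrichment analysis
assumes about an siRNA-treated transcriptome:

* random 3'UTRs with antisense seed-complementary sites planted into a
  controlled fraction of genes (chance occurrences elsewhere are kept and
  recorded — truth is recomputed by scanning, never assumed);
* sense-strand seed sites planted into a disjoint fraction of equal size,
  carrying no expression effect (the negative control is null by
  construction);
* negative-binomial counts for treated/control replicate groups with a strong
  on-target knockdown for full-complement transcripts and mild seed-dependent
  repression for antisense-seed-match genes, truncated so no off-target change
  exceeds twofold;
* optional seed-independent "background" regulation (both directions) so that
  null configurations still produce a non-degenerate downregulated class —
  required to calibrate the enrichment test.

A lightweight DE caller (Welch t-test on log2 CPM with Benjamini-Hochberg
adjustment) stands in for a full negative-binomial Wald framework; it is a
deliberately simple, documented stand-in, not a DESeq2 re-implementation.

Randomness derives from a single ``rng_seed`` via ``numpy.random.SeedSequence``
substreams, one per stage (duplex, UTRs, effects, counts), so identical
configurations reproduce byte-identical outputs at every stage.
"""

from __future__ import annotations


from dataclasses import asdict, dataclass, replace
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .de import classify, join_matches
from .enrich import EnrichmentResult, run_enrichment
from .oligo import (
    ModifiedNucleotide,
    OligoStrand,
    SeedSpec,
    SiRNADuplex,
    reverse_complement,
    seed_site,
)
from .scan import UTRRecord, find_all, scan_set

__all__ = [
    "SyntheticConfig",
    "SyntheticUniverse",
    "generate_universe",
    "generate_counts",
    "call_de",
    "run_pipeline",
    "end_to_end_sim",
    "effect_config",
    "null_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All distributional parameters and the RNG seed for the simulator.

    Defaults describe the reference condition: a 2000-gene transcriptome with
    antisense seed sites planted in 15% of UTRs, mild seed-dependent
    repression (truncated normal, mean -0.6, sd 0.2, capped at |log2FC| = 1,
    i.e. never more than twofold), one full-match on-target gene knocked down
    ~5.7-fold, and 3 vs 3 technical-replicate-like negative-binomial counts:
    baseline means exp(Normal(6, 1)) (~400 counts at the median) with NB size
    1000, i.e. overdispersion 0.001 — near-Poisson, as technical replicates
    of a transfected cell-culture library are.
    """

    n_genes: int = 2000
    utr_length_range: tuple[int, int] = (200, 2000)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    frac_seed_match: float = 0.15
    n_on_target: int = 1
    reps_per_group: int = 3
    mean_log_expression: float = 6.0
    dispersion: float = 1000.0  # NB size parameter; overdispersion = 1/size
    offtarget_lfc_mean: float = -0.6
    offtarget_lfc_sd: float = 0.2
    offtarget_lfc_cap: float = 1.0  # twofold ceiling, |log2FC| units
    ontarget_lfc: float = -2.5
    background_frac: float = 0.0  # seed-independent regulated fraction
    background_lfc_sd: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_seed_match <= 1):
            raise ValueError("frac_seed_match must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be > 0")
        if self.offtarget_lfc_cap < 0:
            raise ValueError("offtarget_lfc_cap must be >= 0")
        if self.reps_per_group < 2:
            raise ValueError("need at least 2 replicates per group")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["utr_length_range"] = list(self.utr_length_range)
        d["base_composition"] = list(self.base_composition)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "utr_length_range" in d:
            d["utr_length_range"] = tuple(d["utr_length_range"])
        if "base_composition" in d:
            d["base_composition"] = tuple(d["base_composition"])
        return cls(**d)


def effect_config(rng_seed: int = 0) -> SyntheticConfig:
    """The reference effect condition (class defaults): planted antisense seed
    sites drive mild repression; sense-seed sites and upregulation stay null."""
    return SyntheticConfig(rng_seed=rng_seed)


def null_config(rng_seed: int = 0) -> SyntheticConfig:
    """Calibration condition: seed sites planted as usual but carrying no
    expression effect (off-target mean and sd zero, no on-target gene).
    Seed-independent background regulation (10% of genes, sd 0.8) keeps the
    downregulated class non-degenerate, so the Fisher null — independence of
    seed match and downregulation — is actually exercised rather than
    trivially returning p = 1 from an empty class."""
    return SyntheticConfig(
        rng_seed=rng_seed,
        offtarget_lfc_mean=0.0,
        offtarget_lfc_sd=0.0,
        n_on_target=0,
        background_frac=0.1,
        background_lfc_sd=0.8,
    )


@dataclass(frozen=True)
class SyntheticUniverse:
    """Generated UTR set, duplex, and per-gene ground truth."""

    utrs: list[UTRRecord]
    duplex: SiRNADuplex
    truth: pd.DataFrame  # gene_id, is_seed_match, is_sense_seed_match, is_on_target


_RNA_BASES = np.array(list("ACGU"))
_DNA_BASES = np.array(list("ACGT"))


def _random_duplex(rng: np.random.Generator) -> SiRNADuplex:
    """Random 21-mer duplex: alternating 2'OMe/2'F, 2-nt 3' overhangs, terminal
    PS linkages, GalNAc on the sense 3' end — the canonical conjugate design."""
    while True:
        as_bases = "".join(rng.choice(_RNA_BASES, size=21))
        sense_paired = reverse_complement(as_bases[:19], alphabet="RNA")
        sense_bases = sense_paired + "".join(rng.choice(_RNA_BASES, size=2))
        duplex = SiRNADuplex(
            antisense=_build_strand(as_bases, first_sugar="2OMe"),
            sense=_build_strand(sense_bases, first_sugar="2F", conjugate="GalNAc"),
            overhang_length=2,
        )
        site_as = seed_site(duplex, SeedSpec("antisense"))
        site_s = seed_site(duplex, SeedSpec("sense"))
        # distinct antisense/sense seed sites keep the negative control clean
        if site_as != site_s:
            return duplex


def _build_strand(bases: str, first_sugar: str, conjugate: str = "none") -> OligoStrand:
    other = "2F" if first_sugar == "2OMe" else "2OMe"
    residues = tuple(
        ModifiedNucleotide(
            base=b,
            sugar=first_sugar if i % 2 == 0 else other,
            linkage_3prime="PS" if i in (0, 1, len(bases) - 3, len(bases) - 2) and i < len(bases) - 1 else "PO",
        )
        for i, b in enumerate(bases)
    )
    return OligoStrand(residues, conjugate_3prime=conjugate)


def _random_utrs(rng: np.random.Generator, config: SyntheticConfig) -> list[str]:
    lo, hi = config.utr_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    total = int(lengths.sum())
    idx = rng.choice(4, size=total, p=np.asarray(config.base_composition))
    big = np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")
    seqs = []
    offset = 0
    for L in lengths:
        seqs.append(big[offset : offset + L])
        offset += L
    return seqs


def _plant(seq: str, site: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(seq) - len(site) + 1))
    return seq[:pos] + site + seq[pos + len(site):]


def generate_universe(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SyntheticUniverse:
    """Generate the UTR set, a random duplex, and ground truth.

    Antisense seed sites are planted into ``frac_seed_match`` of genes and
    sense seed sites into a disjoint fraction of equal size; ``n_on_target``
    genes receive the full-length antisense complement.  Truth flags are then
    recomputed by scanning, so chance occurrences elsewhere are recorded and
    no planted site is taken on faith.
    """
    if rng is None:
        ss = np.random.SeedSequence(config.rng_seed)
        rng_duplex, rng_utr, rng_plant = [np.random.default_rng(c) for c in ss.spawn(3)]
    else:
        rng_duplex = rng_utr = rng_plant = rng
    duplex = _random_duplex(rng_duplex)
    seqs = _random_utrs(rng_utr, config)

    site_as = seed_site(duplex, SeedSpec("antisense"))
    site_s = seed_site(duplex, SeedSpec("sense"))
    full_site = reverse_complement(duplex.antisense.bases, alphabet="DNA")

    n = config.n_genes
    n_plant = int(round(config.frac_seed_match * n))
    if 0 < config.frac_seed_match and n_plant < 1:
        warnings.warn("frac_seed_match * n_genes < 1; no antisense sites planted")
    perm = rng_plant.permutation(n)
    as_idx = perm[:n_plant]
    s_idx = perm[n_plant : 2 * n_plant]
    on_idx = perm[2 * n_plant : 2 * n_plant + config.n_on_target]
    for i in as_idx:
        seqs[i] = _plant(seqs[i], site_as, rng_plant)
    for i in s_idx:
        seqs[i] = _plant(seqs[i], site_s, rng_plant)
    for i in on_idx:
        seqs[i] = _plant(seqs[i], full_site, rng_plant)

    gene_ids = [f"G{i:05d}" for i in range(n)]
    utrs = [UTRRecord(g, s) for g, s in zip(gene_ids, seqs)]

    # ground truth by scanning, not bookkeeping
    is_match = np.array([len(find_all(s, site_as)) > 0 for s in seqs])
    is_sense = np.array([len(find_all(s, site_s)) > 0 for s in seqs])
    is_on = np.array([len(find_all(s, full_site)) > 0 for s in seqs])
    truth = pd.DataFrame(
        {
            "is_seed_match": is_match,
            "is_sense_seed_match": is_sense,
            "is_on_target": is_on,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SyntheticUniverse(utrs=utrs, duplex=duplex, truth=truth)


def _true_lfc(universe: SyntheticUniverse, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene true log2 fold change: on-target knockdown, truncated-normal
    seed-dependent repression (never beyond the twofold cap), optional
    seed-independent background regulation; sense-seed matches contribute 0."""
    n = config.n_genes
    lfc = np.zeros(n)
    match = universe.truth["is_seed_match"].to_numpy()
    on = universe.truth["is_on_target"].to_numpy()
    seed_genes = match & ~on
    k = int(seed_genes.sum())
    if k:
        if config.offtarget_lfc_sd > 0:
            a = (-config.offtarget_lfc_cap - config.offtarget_lfc_mean) / config.offtarget_lfc_sd
            b = (0.0 - config.offtarget_lfc_mean) / config.offtarget_lfc_sd
            draws = stats.truncnorm.rvs(
                a, b, loc=config.offtarget_lfc_mean, scale=config.offtarget_lfc_sd,
                size=k, random_state=rng,
            )
        else:
            draws = np.full(k, np.clip(config.offtarget_lfc_mean, -config.offtarget_lfc_cap, 0.0))
        lfc[seed_genes] = draws
    lfc[on] = config.ontarget_lfc
    if config.background_frac > 0 and config.background_lfc_sd > 0:
        n_bg = int(round(config.background_frac * n))
        bg_idx = rng.permutation(n)[:n_bg]
        lfc[bg_idx] += rng.normal(0.0, config.background_lfc_sd, size=n_bg)
    return lfc


def generate_counts(
    universe: SyntheticUniverse, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts (genes x 2*reps) plus truth extended with true_log2FC.

    Control means are lognormal, exp(Normal(mean_log_expression, 1)); treated
    means are the control means scaled by 2^true_log2FC; both groups share the
    NB size parameter, and library sizes are equal in expectation by
    construction (no normalization offsets are simulated).
    """
    if rng is None:
        ss = np.random.SeedSequence(config.rng_seed)
        rng_effects, rng_counts = [np.random.default_rng(c) for c in ss.spawn(5)[3:]]
    else:
        rng_effects = rng_counts = rng
    lfc = _true_lfc(universe, config, rng_effects)
    n, reps = config.n_genes, config.reps_per_group
    mu_ctrl = np.exp(rng_counts.normal(config.mean_log_expression, 1.0, size=n))
    mu_trt = mu_ctrl * np.power(2.0, lfc)
    size = config.dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        mu_mat = np.repeat(mu[:, None], reps, axis=1)
        return rng_counts.negative_binomial(size, size / (size + mu_mat))

    counts = np.hstack([draw(mu_ctrl), draw(mu_trt)])
    cols = [f"control_{i + 1}" for i in range(reps)] + [f"treated_{i + 1}" for i in range(reps)]
    counts_df = pd.DataFrame(counts, index=universe.truth.index, columns=cols)
    truth = universe.truth.copy()
    truth["true_log2FC"] = lfc
    return counts_df, truth


def _size_factors(mat: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, geometric-mean-normalized to 1.

    Robust to composition shifts (a repressed gene fraction shrinks the
    treated library; total-count scaling would bias every fold change toward
    zero change).  Falls back to total-count scaling when no gene is observed
    in every sample.
    """
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logmat = np.log(mat[positive])
        logref = logmat.mean(axis=1)
        sf = np.exp(np.median(logmat - logref[:, None], axis=0))
    else:
        libsize = mat.sum(axis=0)
        sf = libsize.astype(float)
    return sf / np.exp(np.mean(np.log(sf)))


def call_de(counts: pd.DataFrame, groups: list[str]) -> pd.DataFrame:
    """Simple DE caller: Welch t-test on log2(normalized count + 0.5), BH adjustment.

    Counts are scaled by median-of-ratios size factors; per-gene
    log2FC = log2((mean treated + 0.5) / (mean control + 0.5)) on the
    normalized scale.  Genes with zero variance in both groups get p = 1;
    all-zero genes get a missing padj and drop out of downstream contingency
    tables.  This is a deliberately lightweight stand-in for count-model Wald
    testing, not a re-implementation of it.
    """
    groups = np.asarray(groups)
    if {g for g in groups} != {"control", "treated"}:
        raise ValueError("groups must contain 'control' and 'treated'")
    if min((groups == "control").sum(), (groups == "treated").sum()) < 2:
        raise ValueError("need >= 2 replicates per group")
    mat = counts.to_numpy(float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("sample with zero total counts")
    norm = mat / _size_factors(mat)
    ctrl = norm[:, groups == "control"]
    trt = norm[:, groups == "treated"]
    log2fc = np.log2((trt.mean(axis=1) + 0.5) / (ctrl.mean(axis=1) + 0.5))

    log_ctrl = np.log2(ctrl + 0.5)
    log_trt = np.log2(trt + 0.5)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a precision warning; they get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(log_trt, log_ctrl, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    zero_var = (log_ctrl.var(axis=1) == 0) & (log_trt.var(axis=1) == 0)
    pvals[zero_var] = 1.0
    pvals[np.isnan(pvals)] = 1.0

    all_zero = mat.sum(axis=1) == 0
    padj = np.full(len(pvals), np.nan)
    tested = ~all_zero
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": counts.index.to_numpy(),
            "log2FC": log2fc,
            "pvalue": pvals,
            "padj": padj,
        }
    )


def run_pipeline(
    universe: SyntheticUniverse,
    de_table: pd.DataFrame,
    alpha: float = 0.05,
    specs: list[SeedSpec] | None = None,
    directions: list[str] = ("down", "up"),
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Scan -> classify -> join -> enrich on an existing universe + DE table."""
    specs = specs or [SeedSpec("antisense"), SeedSpec("sense")]
    matches = scan_set(universe.utrs, universe.duplex, specs)
    classes = classify(de_table, alpha=alpha)
    analysis, _ = join_matches(classes, matches)
    return run_enrichment(analysis, specs, directions), analysis


def _single_run(config: SyntheticConfig) -> dict:
    universe = generate_universe(config)
    counts, truth = generate_counts(universe, config)
    groups = ["control"] * config.reps_per_group + ["treated"] * config.reps_per_group
    de_table = call_de(counts, groups)
    results, analysis = run_pipeline(universe, de_table)
    out = {"n_down": int((analysis["label"] == "down").sum())}
    for r in results:
        strand = r.spec_label.split("_")[0]
        out[f"p_{strand}_{r.direction}"] = r.p_one_sided
        out[f"or_{strand}_{r.direction}"] = r.odds_ratio
    # parameter recovery over truly repressed seed-match genes (on-target excluded)
    sel = truth["is_seed_match"] & ~truth["is_on_target"] & (truth["true_log2FC"] < 0)
    est = de_table.set_index("gene_id").loc[truth.index[sel], "log2FC"]
    out["mean_est_lfc_repressed"] = float(est.mean()) if sel.any() else np.nan
    out["mean_true_lfc_repressed"] = (
        float(truth.loc[sel, "true_log2FC"].mean()) if sel.any() else np.nan
    )
    return out


def end_to_end_sim(config: SyntheticConfig, n_sim: int = 1) -> pd.DataFrame:
    """Repeat the full generate -> counts -> DE -> classify -> scan -> enrich
    pipeline ``n_sim`` times with independent child seeds derived from
    ``config.rng_seed``; returns one row of summary statistics per run."""
    child_seeds = np.random.SeedSequence(config.rng_seed).generate_state(n_sim, dtype=np.uint32)
    rows = []
    for s in child_seeds:
        rows.append(_single_run(replace(config, rng_seed=int(s))))
    return pd.DataFrame(rows)


def write_universe(universe: SyntheticUniverse, counts: pd.DataFrame, truth: pd.DataFrame, outdir) -> None:
    """Write FASTA/TSV artifacts that round-trip through the analysis modules."""
    from pathlib import Path

    from .oligo import serialize_strand

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "utrs.fasta", "w") as fh:
        for u in universe.utrs:
            fh.write(f">{u.gene_id}\n{u.sequence}\n")
    pd.DataFrame(
        {
            "duplex_id": ["synthetic-1"],
            "antisense": [serialize_strand(universe.duplex.antisense)],
            "sense": [serialize_strand(universe.duplex.sense)],
            "overhang_length": [universe.duplex.overhang_length],
        }
    ).to_csv(outdir / "duplexes.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
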