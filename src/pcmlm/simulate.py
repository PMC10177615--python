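"""Structured-population genotype and phenotype simulation.

Genotypes follow the Balding–Nichols model: each marker draws an ancestral
frequency p uniformly on ``maf_range``, each population draws its own
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with F the differentiation
parameter (FST), and individuals draw binomial(2, p_pop) dosages.  The
default configuration emulates the study sample this package targets:
94 individuals in 7 discrete populations of sizes 51/12/12/6/6/3/4 with
weak differentiation.

Phenotypes are an additive QTL term, a polygenic term correlated via the
realized genomic kinship of the simulated markers, and Gaussian noise;
each realized component is rescaled to hit its target variance fraction
exactly in-sample.  ``breed_mean_mode`` replaces every individual's value
with its population mean, emulating breed-representative phenotyping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io as gio
from .genotype_io import GenotypeMatrix, GroupAssignment, PhenotypeTable
from .kinship import vanraden_kinship
from .association import GwasConfig, qq_data, run_gwas

logger = logging.getLogger(__name__)

STUDY_POP_SIZES = (51, 12, 12, 6, 6, 3, 4)  # Tibet..wild; n = 94
POP_NAMES = ("Tibet", "Qinghai", "Sichuan", "Gansu", "Xinjiang", "Yunnan", "Wild")
# breeds/genetic resources nested within each region (31 in total): phenotypes
# are shared within breed, which is finer than the compression populations
STUDY_BREEDS_PER_POP = (17, 4, 4, 2, 2, 1, 1)


@dataclass
class SimConfig:
    """Study-condition defaults: 94 samples, 7 weakly differentiated populations."""

    n_pops: int = 7
    pop_sizes: tuple[int, ...] = STUDY_POP_SIZES
    fst: float = 0.05
    m_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 0
    qtl_variance_fraction: float = 0.0
    h2_polygenic: float = 0.3
    breed_mean_mode: bool = False
    breeds_per_pop: tuple[int, ...] | None = STUDY_BREEDS_PER_POP
    seed: int = 0
    n_chrom: int = 5
    chrom_length: int = 50_000_000
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("len(pop_sizes) must equal n_pops")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.qtl_variance_fraction + self.h2_polygenic >= 1.0:
            raise ValueError("qtl_variance_fraction + h2_polygenic must be < 1")
        if self.n_qtl > self.m_markers:
            raise ValueError("n_qtl cannot exceed m_markers")


@dataclass
class PowerReport:
    """Per-strategy empirical power, type-I rate and mean λGC over replicates."""

    methods: dict[str, dict]
    replicates: int
    seeds: list[int]


def simulate_structured_genotypes(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, GroupAssignment]:
    """Balding–Nichols genotypes plus marker table and true population labels."""
    rng = np.random.default_rng(cfg.seed)
    n = sum(cfg.pop_sizes)
    p_anc = rng.uniform(*cfg.maf_range, size=cfg.m_markers)
    codes = np.empty((n, cfg.m_markers))
    row = 0
    pop_labels = []
    for k, size in enumerate(cfg.pop_sizes):
        if cfg.fst > 0:
            a = p_anc * (1.0 - cfg.fst) / cfg.fst
            b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
            p_pop = rng.beta(a, b)
        else:
            p_pop = p_anc
        codes[row : row + size] = rng.binomial(2, p_pop, size=(size, cfg.m_markers))
        name = POP_NAMES[k] if k < len(POP_NAMES) else f"pop{k + 1}"
        pop_labels += [name] * size
        row += size
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = np.nan
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    # uniform positions over n_chrom chromosomes, sorted within chromosome
    chrom = rng.integers(1, cfg.n_chrom + 1, size=cfg.m_markers)
    pos = rng.integers(1, cfg.chrom_length + 1, size=cfg.m_markers)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    codes = codes[:, order]
    markers = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(cfg.m_markers)],
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    g = GenotypeMatrix(sample_ids, codes)
    groups = GroupAssignment(pd.Series(pop_labels, index=sample_ids))
    return g, markers, groups


def simulate_phenotype(
    g: GenotypeMatrix, pops: GroupAssignment, cfg: SimConfig
) -> tuple[np.ndarray, dict]:
    """Additive QTL + kinship-correlated polygenic + noise phenotype.

    Component variances are rescaled to the target fractions exactly
    (in-sample); total variance is 1.  Returns the trait vector and a truth
    record with QTL marker indices and effects.
    """
    rng = np.random.default_rng((cfg.seed + 0x9E37) % 2**31)
    n, m = g.codes.shape
    codes = g.codes
    if np.isnan(codes).any():
        codes = gio.impute_missing_mean(g).codes

    def _scale(v: np.ndarray, target_var: float) -> np.ndarray:
        sd = v.std()
        if sd == 0 or target_var == 0:
            return np.zeros_like(v)
        return (v - v.mean()) * np.sqrt(target_var) / sd

    qtl_idx: list[int] = []
    effects: list[float] = []
    g_qtl = np.zeros(n)
    if cfg.n_qtl > 0:
        freq = codes.mean(axis=0) / 2.0
        eligible = np.flatnonzero((freq >= 0.05) & (freq <= 0.95))
        if eligible.size < cfg.n_qtl:
            raise ValueError("not enough polymorphic markers for requested QTL")
        qtl_idx = sorted(rng.choice(eligible, size=cfg.n_qtl, replace=False).tolist())
        effects = rng.normal(size=cfg.n_qtl).tolist()
        g_qtl = codes[:, qtl_idx] @ np.asarray(effects)
    g_qtl = _scale(g_qtl, cfg.qtl_variance_fraction)

    poly = np.zeros(n)
    if cfg.h2_polygenic > 0:
        kin = vanraden_kinship(GenotypeMatrix(list(g.sample_ids), codes))
        s, u = np.linalg.eigh(kin.values)
        s = np.clip(s, 0.0, None)
        poly = u @ (np.sqrt(s) * rng.normal(size=n))
    poly = _scale(poly, cfg.h2_polygenic)

    noise_var = 1.0 - cfg.qtl_variance_fraction - cfg.h2_polygenic
    noise = _scale(rng.normal(size=n), noise_var)
    y = g_qtl + poly + noise

    breeds = breed_labels(g, pops, cfg)
    if cfg.breed_mean_mode:
        y = pd.Series(y).groupby(breeds.to_numpy()).transform("mean").to_numpy()

    truth = {
        "qtl_indices": qtl_idx,
        "qtl_effects": effects,
        "qtl_variance_fraction": cfg.qtl_variance_fraction,
        "h2_polygenic": cfg.h2_polygenic,
        "breed_labels": breeds.tolist(),
    }
    return y, truth


def breed_labels(
    g: GenotypeMatrix, pops: GroupAssignment, cfg: SimConfig
) -> pd.Series:
    """Deterministic breed labels nested within populations.

    Each population is split into ``breeds_per_pop[k]`` contiguous breeds
    (capped at the population size); when the field does not match the
    population count, one breed per population is used.  Breeds are finer
    than the compression populations, so breed-mean phenotypes still vary
    within a compression group — the regime the provided-group model
    addresses.
    """
    lab = pops.labels.loc[g.sample_ids]
    pop_order = lab.unique().tolist()
    per_pop = cfg.breeds_per_pop
    if per_pop is None or len(per_pop) != len(pop_order):
        per_pop = (1,) * len(pop_order)
    out = pd.Series(index=lab.index, dtype=object)
    for k, pop in enumerate(pop_order):
        ids = lab.index[lab == pop]
        n_breeds = max(1, min(per_pop[k], len(ids)))
        chunks = np.array_split(np.arange(len(ids)), n_breeds)
        for b, chunk in enumerate(chunks):
            out.loc[ids[chunk]] = f"{pop}_b{b + 1}"
    return out


def hudson_fst(g: GenotypeMatrix, pops: GroupAssignment) -> float:
    """Hudson-style FST averaged over markers and population pairs.

    Ratio-of-averages estimator: for each pair of populations,
    N = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),
    D = p1(1−p2) + p2(1−p1); FST = ΣN / ΣD over markers, then averaged
    over pairs.
    """
    labels = pops.labels.loc[g.sample_ids]
    pop_names = labels.unique()
    freqs = {}
    sizes = {}
    for name in pop_names:
        sub = g.codes[(labels == name).to_numpy()]
        freqs[name] = np.nanmean(sub, axis=0) / 2.0
        sizes[name] = (~np.isnan(sub)).sum(axis=0)
    vals = []
    for i in range(len(pop_names)):
        for j in range(i + 1, len(pop_names)):
            p1, p2 = freqs[pop_names[i]], freqs[pop_names[j]]
            n1, n2 = sizes[pop_names[i]], sizes[pop_names[j]]
            ok = (n1 > 1) & (n2 > 1)
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (n1 - 1)
                - p2 * (1 - p2) / (n2 - 1)
            )
            den = p1 * (1 - p2) + p2 * (1 - p1)
            vals.append(float(num[ok].sum() / den[ok].sum()))
    return float(np.mean(vals))


def write_dataset(
    out_dir: str | Path,
    g: GenotypeMatrix,
    markers: pd.DataFrame,
    phen: PhenotypeTable,
    groups: GroupAssignment,
    truth: dict | None = None,
) -> None:
    """Write VCF + phenotype TSV + groups TSV (+ truth JSON) for a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_vcf(out / "genotypes.vcf", g, markers)
    gio.write_phenotypes(out / "phenotypes.tsv", phen)
    gio.write_groups(out / "groups.tsv", groups)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1 - p), 0.0) / n)) if n > 0 else float("nan")


def evaluate_power_typeI(
    cfg: SimConfig,
    methods: list[str],
    reps: int,
    qtl_window: int = 50_000,
    alpha: float = 0.05,
) -> PowerReport:
    """Replicated power / type-I experiment across GWAS strategies.

    Power: fraction of replicates in which any marker within ``qtl_window``
    of a true QTL passes the Bonferroni cutoff.  Type-I: mean fraction of
    markers outside every QTL window with p < 0.05.  pCMLM receives the
    true population labels as its provided grouping.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    hits = {m: 0 for m in methods}
    typei = {m: [] for m in methods}
    lam = {m: [] for m in methods}
    seeds = [(cfg.seed + 1009 * r) % 2**31 for r in range(reps)]
    for r, seed in enumerate(seeds):
        cfg_r = SimConfig(**{**asdict(cfg), "seed": seed})
        g, markers, pops = simulate_structured_genotypes(cfg_r)
        y, truth = simulate_phenotype(g, pops, cfg_r)
        phen = PhenotypeTable(pd.DataFrame({"trait": y}, index=g.sample_ids))
        qtl = markers.iloc[truth["qtl_indices"]][["chrom", "pos"]]
        for method in methods:
            res = run_gwas(
                GwasConfig(
                    trait="trait",
                    strategy=method,
                    genotypes=g,
                    markers=markers,
                    phenotypes=phen,
                    group_assignment=pops if method.lower() == "pcmlm" else None,
                    alpha=alpha,
                )
            )
            near = np.zeros(len(res.records), dtype=bool)
            for _, q in qtl.iterrows():
                near |= (
                    (res.records["chrom"] == q["chrom"])
                    & (res.records["pos"].sub(q["pos"]).abs() <= qtl_window)
                ).to_numpy()
            sig = res.records["p"] < res.threshold
            if len(qtl) and bool((sig & near).any()):
                hits[method] += 1
            null_p = res.records.loc[~near, "p"].dropna()
            if len(null_p):
                typei[method].append(float((null_p < 0.05).mean()))
            lam[method].append(qq_data(res.records)[1])
    summary = {}
    for m in methods:
        power = hits[m] / reps
        t1 = float(np.mean(typei[m])) if typei[m] else float("nan")
        summary[m] = {
            "power": power,
            "power_se": _binomial_se(power, reps),
            "type_i": t1,
            "type_i_se": _binomial_se(t1, reps) if typei[m] else float("nan"),
            "mean_lambda_gc": float(np.mean(lam[m])),
        }
    return PowerReport(methods=summary, replicates=reps, seeds=seeds)
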