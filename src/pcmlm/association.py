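"""GWAS orchestration: MLM, likelihood-searched CMLM and provided-group pCMLM.

The three strategies differ only in where the compression grouping comes
from: ``mlm`` uses singleton groups (no compression), ``cmlm`` searches a
grid of group counts / linkages / operators for the minimum −2LL, and
``pcmlm`` takes the grouping from a user-supplied label file (compress_z)
encoding prior population knowledge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genotype_io as gio
from .genotype_io import (
    GenotypeMatrix,
    GroupAssignment,
    PhenotypeTable,
    QCThresholds,
)
from .kinship import (
    CovariateMatrix,
    KinshipMatrix,
    cluster_kinship,
    compress_kinship,
    pca_components,
    singleton_groups,
    vanraden_kinship,
)
from .mlm import MixedModelFit, fit_null_reml, scan_markers

logger = logging.getLogger(__name__)

STRATEGIES = ("MLM", "CMLM", "pCMLM")

#: −2LL difference below which two compression levels are treated as
#: equivalent: the 5% χ²₁ quantile, i.e. a likelihood gap that would not be
#: significant even for a single extra parameter.  Equivalent levels resolve
#: toward less compression (larger n′), so a flat likelihood profile
#: collapses the search to singleton groups — plain MLM.
NEG2LL_TIE_TOL = 3.84


@dataclass
class CompressionSearchTrace:
    entries: pd.DataFrame  # columns: linkage, operator, n_groups, neg2ll
    chosen_index: int

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("empty search trace")
        chosen = self.entries.iloc[self.chosen_index]["neg2ll"]
        if chosen > self.entries["neg2ll"].min() + NEG2LL_TIE_TOL:
            raise ValueError("chosen entry does not attain the minimum neg2ll")


@dataclass
class GwasResult:
    records: pd.DataFrame
    threshold: float
    significant_ids: list[str]
    strategy: str
    null_fit: MixedModelFit
    covariates: CovariateMatrix
    groups: GroupAssignment
    trace: CompressionSearchTrace | None = None
    qc_report: dict | None = None


@dataclass
class GwasConfig:
    """Inputs for :func:`run_gwas`; file paths or in-memory objects.

    In-memory fields take precedence over paths when both are given.
    """

    trait: str = ""
    strategy: str = "MLM"
    vcf: str | Path | None = None
    pheno: str | Path | None = None
    groups_file: str | Path | None = None
    genotypes: GenotypeMatrix | None = None
    markers: pd.DataFrame | None = None
    phenotypes: PhenotypeTable | None = None
    group_assignment: GroupAssignment | None = None
    n_pcs: int = 3
    alpha: float = 0.05
    qc: QCThresholds = field(default_factory=QCThresholds)
    group_grid: Sequence[int] | None = None
    linkages: Sequence[str] = ("average",)
    operators: Sequence[str] = ("mean",)
    scan_mode: str = "P3D"
    breed_means: bool = False
    out_dir: str | Path | None = None


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise error control: per-marker cutoff alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def default_group_grid(n: int) -> list[int]:
    """Roughly geometric grid of candidate group counts, 1 .. n."""
    grid = [1, 2, 3, 5, 7, 10]
    g = 10
    while g < n:
        g = int(round(g * 1.6))
        grid.append(min(g, n))
    return sorted({min(v, n) for v in grid if v >= 1})


def optimize_compression(
    y: np.ndarray,
    w: CovariateMatrix | np.ndarray,
    kin: KinshipMatrix,
    group_grid: Sequence[int] | None = None,
    linkages: Sequence[str] = ("average",),
    operators: Sequence[str] = ("mean",),
) -> tuple[GroupAssignment, MixedModelFit, CompressionSearchTrace]:
    """Likelihood search over compression settings (classical CMLM).

    Fits the null REML model for every (linkage, operator, n_groups)
    combination and returns the configuration minimising −2LL.  Ties
    (within ``NEG2LL_TIE_TOL``) break toward larger n_groups.
    """
    n = len(kin.sample_ids)
    if group_grid is None:
        group_grid = default_group_grid(n)
    if not group_grid or not linkages or not operators:
        raise ValueError("empty search grid")
    rows = []
    cache: list[tuple[GroupAssignment, MixedModelFit]] = []
    for link in linkages:
        for op in operators:
            for ng in group_grid:
                groups = cluster_kinship(kin, linkage=link, n_groups=int(ng))
                ck = compress_kinship(kin, groups, operator=op)
                fit = fit_null_reml(y, w, ck)
                rows.append((link, op, groups.n_groups, fit.neg2ll))
                cache.append((groups, fit))
    entries = pd.DataFrame(rows, columns=["linkage", "operator", "n_groups", "neg2ll"])
    best = entries["neg2ll"].min()
    tied = entries.index[entries["neg2ll"] <= best + NEG2LL_TIE_TOL]
    chosen = int(max(tied, key=lambda i: (entries.loc[i, "n_groups"], -i)))
    groups, fit = cache[chosen]
    return groups, fit, CompressionSearchTrace(entries, chosen)


def provided_compression(
    groups: GroupAssignment, samples: Sequence[str]
) -> GroupAssignment:
    """Validate a user-provided compress_z assignment against analysis samples.

    Labels for samples absent from the analysis set are dropped with a
    warning; an analysis sample without a label is an error.
    """
    missing = [s for s in samples if s not in groups.labels.index]
    if missing:
        raise KeyError(f"samples without group label: {missing[:5]}")
    extra = groups.labels.index.difference(samples)
    if len(extra):
        logger.warning(
            "provided_compression: %d labelled samples not in analysis set; dropped",
            len(extra),
        )
    sub = groups.labels.loc[list(samples)]
    out = GroupAssignment(sub)
    logger.info("provided_compression: n'=%d groups over %d samples",
                out.n_groups, len(samples))
    return out


def compare_strategies(fit_a: MixedModelFit, fit_b: MixedModelFit) -> float:
    """|−2LL_a − −2LL_b| relative to their mean (the model-agreement score)."""
    a, b = fit_a.neg2ll, fit_b.neg2ll
    mean = (a + b) / 2.0
    if mean <= 0 and a * b < 0:
        raise ValueError("−2LL values of conflicting sign; relative difference undefined")
    if mean == 0:
        return 0.0
    return abs(a - b) / abs(mean)


def qq_data(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Expected vs observed −log10 p pairs and the genomic inflation factor.

    λGC is the median of the χ²₁ statistics implied by the observed p-values
    divided by the null median (≈0.4549).
    """
    p = records["p"].dropna().to_numpy()
    if p.size == 0:
        raise ValueError("no valid p-values")
    obs = np.sort(p)
    m = obs.size
    expected = np.arange(1, m + 1) / (m + 1)
    table = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(obs),
        }
    )
    chi2 = stats.chi2.isf(obs, df=1)
    lambda_gc = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    return table, lambda_gc


def _load_inputs(cfg: GwasConfig) -> tuple[GenotypeMatrix, pd.DataFrame, PhenotypeTable]:
    if cfg.genotypes is not None:
        g, markers = cfg.genotypes, cfg.markers
        if markers is None:
            raise ValueError("in-memory genotypes require a marker table")
    elif cfg.vcf is not None:
        g, markers = gio.read_vcf(cfg.vcf)
    else:
        raise ValueError("no genotype input (vcf or genotypes)")
    if cfg.phenotypes is not None:
        phen = cfg.phenotypes
    elif cfg.pheno is not None:
        phen = gio.read_phenotypes(cfg.pheno)
    else:
        raise ValueError("no phenotype input (pheno or phenotypes)")
    return g, markers, phen


def run_gwas(cfg: GwasConfig) -> GwasResult:
    """Full pipeline: QC → imputation → kinship → PCs → compression → REML → scan.

    Samples with a missing value of the analysed trait are dropped listwise
    before fitting.  Significance uses strict inequality p < alpha/m.
    """
    strategy = cfg.strategy if cfg.strategy in STRATEGIES else cfg.strategy.upper()
    if strategy == "PCMLM":
        strategy = "pCMLM"
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")

    g, markers, phen = _load_inputs(cfg)
    if cfg.trait not in phen.traits:
        raise ValueError(f"trait {cfg.trait!r} not in phenotype table {phen.traits}")
    if cfg.breed_means:
        phen = gio.assign_breed_means(phen)

    # align samples: genotyped ∩ phenotyped with observed trait
    trait = phen.data[cfg.trait]
    keep = [s for s in g.sample_ids if s in trait.index and np.isfinite(trait[s])]
    n_dropped = g.n_samples - len(keep)
    if n_dropped:
        logger.info("run_gwas: dropped %d samples without observed %s", n_dropped, cfg.trait)
    if len(keep) < 3:
        raise ValueError("fewer than 3 samples with genotype and phenotype")
    g = g.take_samples(keep)
    y = trait.loc[keep].to_numpy(dtype=float)

    g_qc, markers_qc, qc_report = gio.apply_marker_qc(g, markers, cfg.qc)
    logger.info("run_gwas[qc]: retained %d/%d markers", qc_report["n_retained"],
                qc_report["n_input"])
    if g_qc.n_markers < 2:
        raise ValueError("fewer than 2 markers survive QC")
    g_imp = gio.impute_missing_mean(g_qc)
    kin = vanraden_kinship(g_imp)
    cov = pca_components(g_imp, k=cfg.n_pcs)
    logger.info("run_gwas[pca]: %d PCs explain %.3f of variance", cfg.n_pcs,
                float(cov.variance_explained.sum()))

    trace = None
    if strategy == "MLM":
        groups = singleton_groups(keep)
        ck = compress_kinship(kin, groups, operator="mean")
        null_fit = fit_null_reml(y, cov, ck)
    elif strategy == "CMLM":
        groups, null_fit, trace = optimize_compression(
            y, cov, kin, cfg.group_grid, cfg.linkages, cfg.operators
        )
        ck = compress_kinship(kin, groups, operator=str(trace.entries.loc[trace.chosen_index, "operator"]))
    else:  # pCMLM
        if cfg.group_assignment is not None:
            provided = cfg.group_assignment
        elif cfg.groups_file is not None:
            provided = gio.read_groups(cfg.groups_file)
        else:
            raise ValueError("pCMLM requires a group assignment (compress_z)")
        groups = provided_compression(provided, keep)
        ck = compress_kinship(kin, groups, operator="mean")
        null_fit = fit_null_reml(y, cov, ck)
    logger.info("run_gwas[fit]: strategy=%s n'=%d Vg=%.4g Ve=%.4g -2LL=%.4f",
                strategy, ck.n_groups, null_fit.components.vg,
                null_fit.components.ve, null_fit.neg2ll)

    records = scan_markers(
        y, cov, g_imp, ck, mode=cfg.scan_mode, null_fit=null_fit, markers=markers_qc
    )
    threshold = bonferroni_threshold(cfg.alpha, g_qc.n_markers)
    significant = records.loc[records["p"] < threshold, "id"].tolist()
    logger.info("run_gwas[scan]: %d/%d markers significant at %.3g",
                len(significant), len(records), threshold)

    result = GwasResult(
        records=records,
        threshold=threshold,
        significant_ids=significant,
        strategy=strategy,
        null_fit=null_fit,
        covariates=cov,
        groups=groups,
        trace=trace,
        qc_report=qc_report,
    )
    if cfg.out_dir is not None:
        write_result(cfg.out_dir, result)
    return result


def write_result(out_dir: str | Path, res: GwasResult) -> None:
    """Write associations, QQ table, search trace and a JSON run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.records.to_csv(out / "associations.tsv", sep="\t", index=False)
    qq, lam = qq_data(res.records)
    qq.to_csv(out / "qq.tsv", sep="\t", index=False)
    if res.trace is not None:
        res.trace.entries.to_csv(out / "search_trace.tsv", sep="\t", index=False)
    summary = {
        "strategy": res.strategy,
        "n_markers": int(len(res.records)),
        "threshold": res.threshold,
        "significant": res.significant_ids,
        "neg2ll": res.null_fit.neg2ll,
        "vg": res.null_fit.components.vg,
        "ve": res.null_fit.components.ve,
        "n_groups": res.groups.n_groups,
        "lambda_gc": lam,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
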