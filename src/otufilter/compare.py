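"""Orchestration of the full filtering-method comparison.

``run_grid`` applies each filtering method independently to the same
baseline table and computes every downstream summary: replicate
reliability, percentage of reads removed, the four alpha-diversity
metrics with significance tests against the unfiltered baseline, phylum
relative abundances, and Bray-Curtis / PCoA / PERMANOVA beta-diversity.
``report`` renders the grid as TSV tables (one per summary family) plus
a single JSON with all numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import OtuTable, OtuTableError, ReplicateDesign, TaxonomyTable
from .diversity import (
    ALPHA_METRICS,
    AlphaDiversityResult,
    DistanceMatrix,
    PcoaResult,
    PermanovaResult,
    alpha_diversity,
    bray_curtis,
    pcoa,
    permanova,
    phylum_relative_abundance,
)
from .filtering import METHOD_LABELS, apply_method
from .reliability import (
    ReliabilityReport,
    percent_reads_removed,
    replicate_agreement,
)

__all__ = ["AlphaComparison", "MethodSummary", "MethodGridResult",
           "compare_alpha", "run_grid", "report"]

DEFAULT_METHOD_PARAMS: dict[str, dict] = {
    "none": {},
    "dataset_relative": {"fraction": 0.001},
    "dataset_max_copies": {"min_exceed": 10},
    "sample_singleton": {},
    "sample_min_copies": {"min_copies": 10},
    "triplicate_max_copies": {"min_copies": 10},
    "triplicate_intersection": {},
}


@dataclass
class AlphaComparison:
    """Two-sample comparison of an alpha metric against the baseline.

    Both a t-test (Welch by default) and the tie-corrected Mann-Whitney
    U with normal approximation are reported; the two-level significance
    flags (p < 0.05 and p < 0.001) follow the t-test p-value.
    """

    t_statistic: float
    t_p_value: float
    u_statistic: float
    u_p_value: float

    @property
    def significant_05(self) -> bool:
        return self.t_p_value < 0.05

    @property
    def significant_001(self) -> bool:
        return self.t_p_value < 0.001

    def marker(self) -> str:
        if self.significant_001:
            return "**"
        if self.significant_05:
            return "*"
        return ""


def compare_alpha(baseline_values, filtered_values, paired: bool = False,
                  equal_var: bool = False) -> AlphaComparison:
    """t-test followed by Mann-Whitney rank-sum comparison of per-sample
    alpha-diversity values.

    Unpaired by default (Welch t; pooled variance via ``equal_var``).
    ``paired=True`` switches to the paired t-test and the Wilcoxon
    signed-rank test, for the replicate-matched design.
    """
    x = np.asarray(baseline_values, dtype=float)
    y = np.asarray(filtered_values, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise OtuTableError("comparisons need at least 3 samples per group")
    if paired:
        if len(x) != len(y):
            raise OtuTableError("paired comparison needs equal-length vectors")
        t_res = stats.ttest_rel(x, y)
        if np.allclose(x, y):
            u_stat, u_p = 0.0, 1.0
        else:
            w = stats.wilcoxon(x, y, zero_method="wilcox", correction=True,
                               mode="approx")
            u_stat, u_p = float(w.statistic), float(w.pvalue)
    else:
        t_res = stats.ttest_ind(x, y, equal_var=equal_var)
        u = stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        u_stat, u_p = float(u.statistic), float(u.pvalue)
    t_stat = float(t_res.statistic)
    t_p = float(t_res.pvalue)
    if math.isnan(t_stat):  # identical constant vectors
        t_stat, t_p = 0.0, 1.0
    return AlphaComparison(t_statistic=t_stat, t_p_value=t_p,
                           u_statistic=u_stat, u_p_value=u_p)


@dataclass
class MethodSummary:
    """All downstream summaries for one filtering method."""

    method: str
    params: dict
    reliability: ReliabilityReport
    pct_reads_removed_mean: float
    pct_reads_removed_se: float
    pct_reads_removed_per_sample: dict[str, float]
    alpha: AlphaDiversityResult
    alpha_vs_baseline: dict[str, AlphaComparison]
    phylum: pd.DataFrame
    distances: DistanceMatrix
    ordination: PcoaResult
    permanova: PermanovaResult
    n_otus: int


@dataclass
class MethodGridResult:
    """Per-method summaries over the shared baseline table."""

    methods: dict[str, MethodSummary]
    baseline_label: str = "none"
    seed: int | None = None

    def __post_init__(self):
        if self.baseline_label not in self.methods:
            raise OtuTableError(
                f"baseline method {self.baseline_label!r} missing from grid")


def run_grid(table: OtuTable, design: ReplicateDesign,
             taxonomy: TaxonomyTable, methods=None, seed: int | None = 0,
             n_permutations: int = 999,
             method_params: dict[str, dict] | None = None,
             relative_beta: bool = True) -> MethodGridResult:
    """Apply each filtering method to the same baseline table and compute
    every downstream summary.

    ``methods`` defaults to all seven; the unfiltered baseline is always
    included (it anchors the significance tests).  Deterministic for a
    given seed: each method's PERMANOVA uses a sub-seed derived from
    ``seed`` and the method's position.

    Beta diversity in the grid is computed on within-sample relative
    abundances by default (``relative_beta``): sequencing depth varies
    several-fold between samples, and raw-count Bray-Curtis would
    attribute that depth variation to composition, swamping the
    individual signal the comparison is about.
    """
    if methods is None:
        methods = list(METHOD_LABELS)
    else:
        methods = list(methods)
        unknown = [m for m in methods if m not in METHOD_LABELS]
        if unknown:
            raise OtuTableError(f"unknown methods: {unknown}")
        if "none" not in methods:
            methods = ["none", *methods]
    params_by_method = dict(DEFAULT_METHOD_PARAMS)
    if method_params:
        for m, p in method_params.items():
            params_by_method[m] = {**params_by_method.get(m, {}), **p}
    design.validate(table, require_triplicates=True)

    summaries: dict[str, MethodSummary] = {}
    baseline_alpha: AlphaDiversityResult | None = None
    for k, method in enumerate(methods):
        params = params_by_method.get(method, {})
        try:
            fr = apply_method(method, table, design=design, **params)
            mean_rm, se_rm, per_sample_rm = percent_reads_removed(fr, table)
            rel = replicate_agreement(fr.table, design)
            alpha = alpha_diversity(fr.table)
            phylum = phylum_relative_abundance(fr.table, taxonomy)
            dm = bray_curtis(fr.table, relative=relative_beta)
            ord_res = pcoa(dm)
            sub_seed = None if seed is None else (int(seed) * 1000 + k) % (2 ** 31)
            perm = permanova(dm, design.labels_for(fr.table.sample_ids),
                             n_permutations=n_permutations, seed=sub_seed)
        except OtuTableError as exc:
            raise OtuTableError(f"method {method!r}: {exc}") from exc
        comparisons: dict[str, AlphaComparison] = {}
        if method == "none":
            baseline_alpha = alpha
        summaries[method] = MethodSummary(
            method=method, params=params, reliability=rel,
            pct_reads_removed_mean=mean_rm, pct_reads_removed_se=se_rm,
            pct_reads_removed_per_sample=per_sample_rm,
            alpha=alpha, alpha_vs_baseline=comparisons, phylum=phylum,
            distances=dm, ordination=ord_res, permanova=perm,
            n_otus=fr.table.n_otus,
        )
    assert baseline_alpha is not None
    for method, summary in summaries.items():
        if method == "none":
            continue
        for metric in ALPHA_METRICS:
            summary.alpha_vs_baseline[metric] = compare_alpha(
                baseline_alpha.values(metric), summary.alpha.values(metric))
    return MethodGridResult(methods=summaries, seed=seed)


# -- rendering -------------------------------------------------------------

def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def report(grid: MethodGridResult, outdir) -> dict[str, str]:
    """Write the grid as reliability / alpha-diversity / phylum TSV
    tables, per-method PCoA coordinates, and one JSON with all numbers.

    Re-running on the same result reproduces the files byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    rows = []
    for m, s in grid.methods.items():
        r3, r2, r1 = s.reliability.mean
        e3, e2, e1 = s.reliability.se
        rows.append({
            "method": m,
            "pct_otus_in_3_mean": _fmt(r3), "pct_otus_in_3_se": _fmt(e3),
            "pct_otus_in_2_mean": _fmt(r2), "pct_otus_in_2_se": _fmt(e2),
            "pct_otus_in_1_mean": _fmt(r1), "pct_otus_in_1_se": _fmt(e1),
            "pct_reads_removed_mean": _fmt(s.pct_reads_removed_mean),
            "pct_reads_removed_se": _fmt(s.pct_reads_removed_se),
        })
    p = outdir / "reliability_by_method.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["reliability"] = str(p)

    rows = []
    for m, s in grid.methods.items():
        row = {"method": m}
        for metric in ALPHA_METRICS:
            row[f"{metric}_mean"] = _fmt(s.alpha.mean[metric])
            row[f"{metric}_se"] = _fmt(s.alpha.se[metric])
            cmp_res = s.alpha_vs_baseline.get(metric)
            row[f"{metric}_sig"] = cmp_res.marker() if cmp_res else ""
        rows.append(row)
    p = outdir / "alpha_by_method.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["alpha"] = str(p)

    rows = []
    for m, s in grid.methods.items():
        for phylum in s.phylum.index:
            rows.append({
                "method": m, "phylum": phylum,
                "mean_pct": _fmt(float(s.phylum.loc[phylum, "mean"])),
                "se_pct": _fmt(float(s.phylum.loc[phylum, "se"])),
            })
    p = outdir / "phylum_by_method.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["phylum"] = str(p)

    for m, s in grid.methods.items():
        p = outdir / f"pcoa_{m}.tsv"
        df = s.ordination.to_frame().round(10)
        df.index.name = "sample_id"
        df.to_csv(p, sep="\t")
        paths[f"pcoa_{m}"] = str(p)

    blob = {"seed": grid.seed, "baseline": grid.baseline_label, "methods": {}}
    for m, s in grid.methods.items():
        blob["methods"][m] = {
            "params": s.params,
            "n_otus": s.n_otus,
            "reliability_mean": list(s.reliability.mean),
            "reliability_se": list(s.reliability.se),
            "pct_reads_removed_mean": s.pct_reads_removed_mean,
            "pct_reads_removed_se": s.pct_reads_removed_se,
            "alpha_mean": s.alpha.mean,
            "alpha_se": s.alpha.se,
            "alpha_vs_baseline": {
                metric: {
                    "t": c.t_statistic, "t_p": c.t_p_value,
                    "u": c.u_statistic, "u_p": c.u_p_value,
                    "marker": c.marker(),
                } for metric, c in s.alpha_vs_baseline.items()
            },
            "phylum_mean_pct": {ph: float(s.phylum.loc[ph, "mean"])
                                for ph in s.phylum.index},
            "permanova": {
                "r_squared": s.permanova.r_squared,
                "pseudo_f": s.permanova.pseudo_f,
                "p_value": s.permanova.p_value,
                "n_permutations": s.permanova.n_permutations,
                "seed": s.permanova.seed,
            },
        }
    p = outdir / "grid_summary.json"
    with p.open("w") as fh:
        json.dump(blob, fh, indent=1, sort_keys=True)
    paths["json"] = str(p)
    return paths


def load_report(path) -> dict:
    """Load the JSON written by :func:`report`."""
    with Path(path).open() as fh:
        return json.load(fh)
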