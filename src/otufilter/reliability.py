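"""Replicate-agreement (reliability) statistics and per-OTU variability.

Reliability is the percentage of OTUs, among those detected in at least
one replicate of a specimen, that are detected in all three replicates.
Each specimen contributes one percentage; the aggregate is the mean with
its standard error across specimens.

Quantification precision is summarised by the coefficient of variation
(CV): the standard deviation of an OTU's copy counts across a specimen's
three replicates divided by their mean, with absent replicates counted
as zeros.  CVs and detection reliability are stratified by abundance —
by copy-count bins for CV and by relative-abundance bins for
reliability — to show that abundant OTUs are quantified precisely and
detected consistently while rare ones are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FilterResult, OtuTable, OtuTableError, ReplicateDesign

__all__ = [
    "AbundanceBinScheme",
    "ReliabilityReport",
    "replicate_agreement",
    "percent_reads_removed",
    "otu_cv",
    "cv_by_abundance_bin",
    "reliability_by_abundance_bin",
    "abundance_bin_summary",
]

SPORADIC = "sporadic"


@dataclass(frozen=True)
class AbundanceBinScheme:
    """Bin edges for abundance stratification.

    ``relative_edges`` are relative-abundance cut points (descending);
    the default (0.01, 0.001, 0.0001) yields bins >1%, 0.1-1%,
    0.01-0.1%, <0.01%.  ``copy_edges`` are copy-count cut points for the
    CV bins; the default (1000, 100, 10, 1) yields >1000, 100-1000,
    10-100 and 1-10 copies, plus a "sporadic" bin for OTUs detected in
    at most two replicates with fewer than ``sporadic_max_copies``
    copies.  Bin boundaries are lower-edge inclusive, upper-edge
    exclusive (e.g. exactly 1% falls in the 0.1-1% bin).
    """

    relative_edges: tuple[float, ...] = (0.01, 0.001, 0.0001)
    copy_edges: tuple[float, ...] = (1000.0, 100.0, 10.0, 1.0)
    sporadic_max_copies: float = 10.0

    def __post_init__(self):
        for edges in (self.relative_edges, self.copy_edges):
            if not edges or any(lo >= hi for hi, lo in zip(edges, edges[1:])):
                raise OtuTableError("bin edges must be strictly decreasing")
            if any(e <= 0 for e in edges):
                raise OtuTableError("bin edges must be positive")

    # labels, most abundant first
    def relative_labels(self) -> list[str]:
        labels = [f">{self.relative_edges[0] * 100:g}%"]
        for hi, lo in zip(self.relative_edges, self.relative_edges[1:]):
            labels.append(f"{lo * 100:g}-{hi * 100:g}%")
        labels.append(f"<{self.relative_edges[-1] * 100:g}%")
        return labels

    def copy_labels(self) -> list[str]:
        labels = [f">{self.copy_edges[0]:g}"]
        for hi, lo in zip(self.copy_edges, self.copy_edges[1:]):
            labels.append(f"{lo:g}-{hi:g}")
        return labels + [SPORADIC]

    def relative_bin(self, value: float) -> str:
        """Bin label for a relative abundance (lower edge inclusive)."""
        labels = self.relative_labels()
        for i, edge in enumerate(self.relative_edges):
            if value >= edge:
                return labels[i]
        return labels[-1]

    def copy_bin(self, mean_copies: float) -> str:
        labels = self.copy_labels()
        for i, edge in enumerate(self.copy_edges):
            if mean_copies >= edge:
                return labels[i]
        return labels[-2]  # below the last edge but not sporadic


@dataclass
class ReliabilityReport:
    """Per-specimen and aggregated replicate-agreement percentages.

    ``per_specimen`` maps specimen -> (%_in_3, %_in_2, %_in_1); the
    three percentages sum to 100 for every specimen with a non-empty
    union of detected OTUs.  Aggregates are means with standard errors
    (sd / sqrt(n_specimens)) across specimens.
    """

    per_specimen: dict[str, tuple[float, float, float]]
    mean: tuple[float, float, float]
    se: tuple[float, float, float]
    empty_specimens: list[str] = field(default_factory=list)

    @property
    def pct_in_three(self) -> float:
        return self.mean[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            self.per_specimen, orient="index",
            columns=["pct_in_3", "pct_in_2", "pct_in_1"],
        )
        df.index.name = "specimen"
        return df


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error (sample sd / sqrt(n))."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return math.nan, math.nan
    if n == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(n))


def replicate_agreement(table: OtuTable, design: ReplicateDesign) -> ReliabilityReport:
    """Classify each specimen's detected OTUs by how many of the three
    replicates they appear in.

    For each specimen the unit set is the union of OTUs with count >= 1
    in at least one replicate; each unit is classified as detected in 3,
    2 or 1 replicates and the three classes are reported as percentages
    of the unit set.  Specimens whose union is empty contribute nothing
    and are flagged in ``empty_specimens``.
    """
    design.validate(table, require_triplicates=True)
    counts = table.counts
    col = {s: j for j, s in enumerate(table.sample_ids)}
    in_table = set(table.sample_ids)
    per_specimen: dict[str, tuple[float, float, float]] = {}
    empty: list[str] = []
    for spec, samples in design.groups().items():
        cols = [col[s] for s in samples if s in in_table]
        detected = counts[:, cols] >= 1
        n_reps = detected.sum(axis=1)
        union = int((n_reps >= 1).sum())
        if union == 0:
            empty.append(spec)
            continue
        pct = tuple(100.0 * float((n_reps == k).sum()) / union for k in (3, 2, 1))
        per_specimen[spec] = pct
    if not per_specimen:
        raise OtuTableError("no specimen has any detected OTU")
    arr = np.array(list(per_specimen.values()), dtype=float)
    means, ses = zip(*(_mean_se(arr[:, k]) for k in range(3)))
    return ReliabilityReport(
        per_specimen=per_specimen, mean=tuple(means), se=tuple(ses),
        empty_specimens=empty,
    )


def percent_reads_removed(filter_result: FilterResult,
                          baseline_table: OtuTable) -> tuple[float, float, dict[str, float]]:
    """Percentage of reads a filter removed, per sample and aggregated.

    Returns ``(mean, se, per_sample)`` where each sample contributes
    ``100 * reads_removed / baseline_total`` and the aggregate is the
    mean with SE over samples.
    """
    removed = filter_result.reads_removed_per_sample
    missing = [s for s in baseline_table.sample_ids if s not in removed]
    if missing:
        raise OtuTableError(f"filter result lacks samples: {missing}")
    per_sample: dict[str, float] = {}
    baseline = baseline_table.to_dataframe().sum(axis=0)
    for s in baseline_table.sample_ids:
        total = int(baseline[s])
        if total == 0:
            raise OtuTableError(f"baseline total is 0 for sample {s!r}")
        per_sample[s] = 100.0 * removed[s] / total
    mean, se = _mean_se(np.array(list(per_sample.values())))
    return mean, se, per_sample


def otu_cv(table: OtuTable, design: ReplicateDesign, specimen: str,
           otu_id: str, ddof: int = 1) -> float:
    """Coefficient of variation of one OTU's copy counts within a
    specimen's triplicate.

    CV = sd / mean over the three replicate counts, absences counted as
    zeros.  ``ddof=1`` (sample sd, the common software default) gives
    sqrt(3) for a single-replicate detection such as (10, 0, 0);
    ``ddof=0`` (population sd) gives sqrt(2).
    """
    design.validate(table, require_triplicates=True)
    samples = [s for s in design.samples_of(specimen) if s in set(table.sample_ids)]
    if not samples:
        raise OtuTableError(f"unknown specimen {specimen!r}")
    if otu_id not in set(table.otu_ids):
        raise OtuTableError(f"unknown OTU {otu_id!r}")
    row = table.to_dataframe().loc[otu_id, samples].to_numpy(dtype=float)
    return _cv(row, ddof)


def _cv(values: np.ndarray, ddof: int) -> float:
    mean = values.mean()
    if mean == 0:
        raise OtuTableError("CV undefined: OTU absent from all replicates")
    return float(values.std(ddof=ddof) / mean)


def _triplicate_blocks(table: OtuTable, design: ReplicateDesign):
    """Yield (specimen, counts block of shape (n_otus, 3))."""
    design.validate(table, require_triplicates=True)
    counts = table.counts
    col = {s: j for j, s in enumerate(table.sample_ids)}
    in_table = set(table.sample_ids)
    for spec, samples in design.groups().items():
        cols = [col[s] for s in samples if s in in_table]
        yield spec, counts[:, cols]


def cv_by_abundance_bin(table: OtuTable, design: ReplicateDesign,
                        scheme: AbundanceBinScheme | None = None,
                        ddof: int = 1) -> dict[str, float]:
    """Mean CV per copy-count bin over all (specimen, OTU) units.

    Each unit detected in at least one replicate is assigned to the
    sporadic bin when it is detected in at most two replicates with
    every count below ``scheme.sporadic_max_copies``; otherwise it is
    binned by its mean copies across the triplicate.  Empty bins are
    omitted from the result.
    """
    scheme = scheme or AbundanceBinScheme()
    sums: dict[str, list[float]] = {}
    for _spec, block in _triplicate_blocks(table, design):
        block = block.astype(float)
        n_det = (block >= 1).sum(axis=1)
        means = block.mean(axis=1)
        sds = block.std(axis=1, ddof=ddof)
        maxes = block.max(axis=1)
        for i in np.nonzero(n_det >= 1)[0]:
            if n_det[i] <= 2 and maxes[i] < scheme.sporadic_max_copies:
                label = SPORADIC
            else:
                label = scheme.copy_bin(means[i])
            sums.setdefault(label, []).append(sds[i] / means[i])
    return {
        label: float(np.mean(sums[label]))
        for label in scheme.copy_labels() if label in sums
    }


def reliability_by_abundance_bin(table: OtuTable, design: ReplicateDesign,
                                 scheme: AbundanceBinScheme | None = None
                                 ) -> dict[str, float]:
    """Percentage of (specimen, OTU) units detected in all three
    replicates, stratified by mean relative abundance within the
    specimen.

    Units are binned by the mean over the three replicates of their
    within-sample relative abundance.  Empty bins are omitted rather
    than reported as 0.
    """
    scheme = scheme or AbundanceBinScheme()
    tallies: dict[str, list[int]] = {}
    for _spec, block in _triplicate_blocks(table, design):
        totals = block.sum(axis=0)
        if (totals == 0).any():
            raise OtuTableError("replicate with zero total reads")
        rel = block / totals
        mean_rel = rel.mean(axis=1)
        n_det = (block >= 1).sum(axis=1)
        for i in np.nonzero(n_det >= 1)[0]:
            label = scheme.relative_bin(mean_rel[i])
            tallies.setdefault(label, []).append(int(n_det[i] == 3))
    return {
        label: 100.0 * float(np.mean(tallies[label]))
        for label in scheme.relative_labels() if label in tallies
    }


def abundance_bin_summary(table: OtuTable,
                          scheme: AbundanceBinScheme | None = None) -> pd.DataFrame:
    """Mean number of detected OTUs and mean share of reads per
    relative-abundance bin, averaged over samples.

    Within each sample, detected OTUs are binned by their within-sample
    relative abundance; the per-bin OTU counts and read shares are then
    averaged across samples.  Returns a DataFrame indexed by bin label
    with columns ``mean_otus``, ``se_otus``, ``mean_pct_reads``,
    ``se_pct_reads``.
    """
    scheme = scheme or AbundanceBinScheme()
    labels = scheme.relative_labels()
    counts = table.counts
    n_otus_per_bin = {lab: [] for lab in labels}
    pct_reads_per_bin = {lab: [] for lab in labels}
    for j in range(table.n_samples):
        col = counts[:, j]
        total = col.sum()
        if total == 0:
            raise OtuTableError(
                f"sample {table.sample_ids[j]!r} has zero total reads"
            )
        rel = col / total
        binned = {lab: (0, 0.0) for lab in labels}
        for i in np.nonzero(col >= 1)[0]:
            lab = scheme.relative_bin(rel[i])
            n, share = binned[lab]
            binned[lab] = (n + 1, share + rel[i])
        for lab in labels:
            n, share = binned[lab]
            n_otus_per_bin[lab].append(n)
            pct_reads_per_bin[lab].append(100.0 * share)
    rows = []
    for lab in labels:
        mean_n, se_n = _mean_se(np.array(n_otus_per_bin[lab]))
        mean_p, se_p = _mean_se(np.array(pct_reads_per_bin[lab]))
        rows.append((lab, mean_n, se_n, mean_p, se_p))
    df = pd.DataFrame(
        rows, columns=["bin", "mean_otus", "se_otus", "mean_pct_reads", "se_pct_reads"]
    ).set_index("bin")
    return df
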