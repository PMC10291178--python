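"""Low-abundance OTU filtering methods.

Seven methods are implemented, differing in the *scope* at which the
abundance criterion is evaluated:

==========================  ==========================================
label                       criterion
==========================  ==========================================
none                        identity baseline — all OTUs included
dataset_relative            OTU removed from ALL samples if its pooled
                            share of the grand total is < ``fraction``
                            (default 0.1%)
dataset_max_copies          OTU removed from ALL samples unless it has
                            > ``min_exceed`` copies (strictly) in at
                            least one sample
sample_singleton            cells equal to 1 are zeroed, per sample
sample_min_copies           cells with 1 <= count < ``min_copies`` are
                            zeroed, per sample
triplicate_max_copies       per specimen, OTU zeroed in all three
                            replicates unless it has >= ``min_copies``
                            in at least one of them
triplicate_intersection     per specimen, OTU zeroed in all three
                            replicates unless detected (count >= 1) in
                            every one of them
==========================  ==========================================

Dataset-scope criteria delete the OTU row everywhere; sample- and
triplicate-scope criteria zero cells and then drop rows that became
all-zero.  The strictness of each comparison follows the criterion
wording exactly: dataset-scope ">10 copies" is strict, triplicate-scope
">=10 copies" is non-strict, and "<10 copies" removes counts 1-9 (a
``<= 10`` reading is expressible as ``min_copies=11``).

Every result satisfies per-sample read conservation
(pre-filter total = post-filter total + reads removed) and every method
is idempotent.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import FilterResult, OtuTable, OtuTableError, ReplicateDesign

__all__ = [
    "METHOD_LABELS",
    "filter_none",
    "filter_dataset_relative",
    "filter_dataset_max_copies",
    "filter_sample_singleton",
    "filter_sample_min_copies",
    "filter_triplicate_max_copies",
    "filter_triplicate_intersection",
    "apply_method",
]

METHOD_LABELS = (
    "none",
    "dataset_relative",
    "dataset_max_copies",
    "sample_singleton",
    "sample_min_copies",
    "triplicate_max_copies",
    "triplicate_intersection",
)


def _result(table: OtuTable, new_counts: np.ndarray, label: str,
            drop_empty: bool = True) -> FilterResult:
    """Assemble a FilterResult from the original table and zeroed counts."""
    old = table.counts
    removed = old - new_counts
    if (removed < 0).any():
        raise AssertionError("filter increased a count")  # internal invariant
    reads_removed = {
        s: int(removed[:, j].sum()) for j, s in enumerate(table.sample_ids)
    }
    zeroed_mask = (old >= 1) & (new_counts == 0)
    otus = np.array(table.otu_ids, dtype=object)
    otus_zeroed = {
        s: set(otus[zeroed_mask[:, j]]) for j, s in enumerate(table.sample_ids)
    }
    filtered = OtuTable(new_counts, otu_ids=table.otu_ids,
                        sample_ids=table.sample_ids)
    if drop_empty:
        filtered = filtered.drop_empty_otus()
    return FilterResult(
        table=filtered,
        reads_removed_per_sample=reads_removed,
        otus_zeroed=otus_zeroed,
        method_label=label,
    )


def filter_none(table: OtuTable) -> FilterResult:
    """Identity baseline: all OTUs included, zero reads removed."""
    counts = table.counts
    return _result(table, counts, "none", drop_empty=False)


def filter_dataset_relative(table: OtuTable, fraction: float = 0.001) -> FilterResult:
    """Remove OTUs whose pooled relative abundance is below ``fraction``.

    The criterion pools counts over all samples: an OTU is removed from
    every sample when pooled_count / grand_total < fraction (strict, so
    an OTU sitting exactly at the threshold is kept).  Equivalently the
    copy threshold is ``fraction * grand_total``: 10,000 copies for a
    10,000,000-read dataset but only 1,000 for a 1,000,000-read one —
    the method's threshold scales with study size.
    """
    if not 0.0 < fraction < 1.0:
        raise OtuTableError(f"fraction must be in (0, 1), got {fraction}")
    counts = table.counts
    grand_total = counts.sum()
    if grand_total == 0:
        raise OtuTableError("cannot apply a relative-abundance filter to an "
                            "all-zero table (grand total is 0)")
    pooled = counts.sum(axis=1)
    remove = pooled < fraction * grand_total
    new_counts = counts.copy()
    new_counts[remove, :] = 0
    return _result(table, new_counts, "dataset_relative")


def filter_dataset_max_copies(table: OtuTable, min_exceed: int = 10) -> FilterResult:
    """Remove OTUs lacking > ``min_exceed`` copies in at least one sample.

    An OTU is kept (in every sample, zeros included) iff its maximum
    per-sample count strictly exceeds ``min_exceed``.
    """
    if min_exceed < 0:
        raise OtuTableError(f"min_exceed must be >= 0, got {min_exceed}")
    counts = table.counts
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        return _result(table, counts, "dataset_max_copies")
    keep = counts.max(axis=1) > min_exceed
    new_counts = counts.copy()
    new_counts[~keep, :] = 0
    return _result(table, new_counts, "dataset_max_copies")


def filter_sample_singleton(table: OtuTable) -> FilterResult:
    """Zero every cell equal to exactly 1 (per-sample singletons)."""
    counts = table.counts
    new_counts = np.where(counts == 1, 0, counts)
    return _result(table, new_counts, "sample_singleton")


def filter_sample_min_copies(table: OtuTable, min_copies: int = 10) -> FilterResult:
    """Zero cells with fewer than ``min_copies`` copies, per sample.

    Counts in ``1 <= count < min_copies`` are set to 0; ``min_copies=2``
    is the singleton filter, ``min_copies=1`` the identity.
    """
    if min_copies < 1:
        raise OtuTableError(f"min_copies must be >= 1, got {min_copies}")
    counts = table.counts
    new_counts = np.where(counts < min_copies, 0, counts)
    return _result(table, new_counts, "sample_min_copies")


def _triplicate_groups(table: OtuTable, design: ReplicateDesign) -> dict[str, list[int]]:
    """Column indices per specimen, enforcing exactly three replicates."""
    design.validate(table, require_triplicates=True)
    col = {s: j for j, s in enumerate(table.sample_ids)}
    in_table = set(table.sample_ids)
    return {
        spec: [col[s] for s in samples if s in in_table]
        for spec, samples in design.groups().items()
    }


def filter_triplicate_max_copies(table: OtuTable, design: ReplicateDesign,
                                 min_copies: int = 10) -> FilterResult:
    """Within each specimen, zero an OTU in all three replicates unless it
    reaches >= ``min_copies`` copies in at least one of them.

    The criterion is non-strict (a single replicate at exactly
    ``min_copies`` keeps the OTU) and decided independently per specimen.
    """
    if min_copies < 1:
        raise OtuTableError(f"min_copies must be >= 1, got {min_copies}")
    counts = table.counts
    new_counts = counts.copy()
    for cols in _triplicate_groups(table, design).values():
        block = counts[:, cols]
        zero = block.max(axis=1) < min_copies
        sub = new_counts[:, cols]
        sub[zero, :] = 0
        new_counts[:, cols] = sub
    return _result(table, new_counts, "triplicate_max_copies")


def filter_triplicate_intersection(table: OtuTable,
                                   design: ReplicateDesign) -> FilterResult:
    """Within each specimen, keep an OTU only if it is detected
    (count >= 1) in every one of the three replicates.

    After this filter, every OTU still present in a specimen appears in
    all three of its replicates, so the three-replicate agreement is
    100% by construction.
    """
    counts = table.counts
    new_counts = counts.copy()
    for cols in _triplicate_groups(table, design).values():
        block = counts[:, cols]
        zero = (block >= 1).sum(axis=1) < len(cols)
        sub = new_counts[:, cols]
        sub[zero, :] = 0
        new_counts[:, cols] = sub
    return _result(table, new_counts, "triplicate_intersection")


def apply_method(label: str, table: OtuTable,
                 design: ReplicateDesign | None = None, **params) -> FilterResult:
    """Dispatch a filtering method by label.

    Triplicate-scope methods require ``design``; parameters (``fraction``,
    ``min_exceed``, ``min_copies``) pass through to the method.
    """
    sample_scope: dict[str, Callable] = {
        "none": filter_none,
        "dataset_relative": filter_dataset_relative,
        "dataset_max_copies": filter_dataset_max_copies,
        "sample_singleton": filter_sample_singleton,
        "sample_min_copies": filter_sample_min_copies,
    }
    if label in sample_scope:
        return sample_scope[label](table, **params)
    if label == "triplicate_max_copies":
        if design is None:
            raise OtuTableError("triplicate_max_copies requires a replicate design")
        return filter_triplicate_max_copies(table, design, **params)
    if label == "triplicate_intersection":
        if design is None:
            raise OtuTableError("triplicate_intersection requires a replicate design")
        return filter_triplicate_intersection(table, design, **params)
    raise OtuTableError(f"unknown filtering method {label!r}; "
                        f"expected one of {METHOD_LABELS}")
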