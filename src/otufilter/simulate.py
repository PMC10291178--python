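"""Synthetic 16S OTU tables with triplicate structure and spurious OTUs.

The generator emulates the structure of a processed stool amplicon
dataset: a dozen individuals, three technical replicates each, a
heavy-tailed (lognormal) core community shared across individuals but
perturbed per individual, sequencing depths drawn from a clamped
normal, multinomial read sampling within each replicate, and — the
feature the reliability analysis turns on — replicate-specific spurious
OTUs: low-copy artifact taxa drawn independently per replicate from a
large pool, standing in for PCR/sequencing error.  Because spurious
OTUs rarely recur across replicates, they drive the fraction of OTUs
detected in only one of the three replicates.

Ground truth (each specimen's true composition and the injected
spurious OTU ids per sample) is carried alongside the observable data
so every downstream stage can be tested against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    OtuTable,
    OtuTableError,
    ReplicateDesign,
    TaxonomyTable,
    write_design,
    write_shared,
    write_taxonomy,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "generate",
           "calibration_report", "write_dataset"]

DEFAULT_PHYLUM_MIXTURE = {
    "Firmicutes": 0.726,
    "Bacteroidetes": 0.186,
    "Verrucomicrobia": 0.052,
    "Actinobacteria": 0.027,
    "Proteobacteria": 0.006,
    "other": 0.003,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic community.

    Defaults reproduce the structure of a 12-individual triplicate stool
    study: ~40,572 reads per sample (SD 10,883, clamped to the observed
    24,776-74,720 range), a lognormal core community of 300 OTUs whose
    dominant members carry most of the reads, a phylum mixture led by
    Firmicutes (72.6%) and Bacteroidetes (18.6%), and enough
    replicate-specific spurious OTUs that roughly 40% of the OTUs
    detected within a triplicate appear in only one replicate.

    ``individuality`` is the Dirichlet concentration multiplier applied
    to the core profile when drawing each specimen's own composition:
    smaller values give more divergent individuals.  ``spurious_rate``
    is the expected number of spurious OTUs injected per replicate, each
    drawn from a pool of ``spurious_pool_size`` artifact taxa with
    copy numbers geometric on {1, 2, ...} with mean
    ``spurious_copy_mean``; a small fraction
    ``spurious_high_fraction`` of them are high-copy artifacts
    (chimera/contamination-like, >= 10 copies), which is why a handful
    of replicate-unique OTUs survive even copy-number-based triplicate
    filters.

    ``replicate_noise`` is the standard deviation of a multiplicative
    lognormal perturbation applied to the specimen profile before each
    replicate is sequenced.  It models subsampling, pipetting and PCR
    variability between aliquots of one specimen: with pure multinomial
    resampling the CV of abundant OTUs across replicates would be an
    order of magnitude below what replicate studies observe, and
    abundance-based filters would look artificially perfect.
    """

    n_specimens: int = 12
    replicates_per_specimen: int = 3
    n_core_otus: int = 300
    lognormal_sigma: float = 2.3
    depth_mean: float = 40572.0
    depth_sd: float = 10883.0
    depth_within_sd: float = 2000.0
    depth_min: int = 24776
    depth_max: int = 74720
    spurious_pool_size: int = 3000
    spurious_rate: float = 40.0
    spurious_copy_mean: float = 1.5
    spurious_high_fraction: float = 0.02
    phylum_mixture: dict = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_MIXTURE))
    individuality: float = 600.0
    replicate_noise: float = 0.05
    seed: int | None = None

    def validate(self) -> None:
        if self.n_specimens < 1 or self.replicates_per_specimen < 2:
            raise OtuTableError("need >=1 specimen and >=2 replicates each")
        if self.n_core_otus < 1:
            raise OtuTableError("n_core_otus must be positive")
        if self.lognormal_sigma <= 0:
            raise OtuTableError("lognormal_sigma must be positive")
        if self.depth_min <= 0:
            raise OtuTableError("depth_min must be positive")
        if not (self.depth_min <= self.depth_mean <= self.depth_max):
            raise OtuTableError(
                "infeasible depth clamps: require depth_min <= depth_mean "
                f"<= depth_max, got {self.depth_min} / {self.depth_mean} / "
                f"{self.depth_max}"
            )
        if self.depth_sd < 0:
            raise OtuTableError("depth_sd must be non-negative")
        if not 0 <= self.depth_within_sd <= self.depth_sd:
            raise OtuTableError(
                "depth_within_sd must be in [0, depth_sd]: the "
                "within-triplicate spread is one component of the overall "
                "per-sample depth spread")
        if self.spurious_rate < 0:
            raise OtuTableError("spurious_rate must be >= 0")
        if self.spurious_pool_size < 1:
            raise OtuTableError("spurious_pool_size must be positive")
        if self.spurious_copy_mean < 1.0:
            raise OtuTableError("spurious_copy_mean must be >= 1")
        if not 0.0 <= self.spurious_high_fraction <= 1.0:
            raise OtuTableError("spurious_high_fraction must be in [0, 1]")
        if self.individuality <= 0:
            raise OtuTableError("individuality must be positive")
        if self.replicate_noise < 0:
            raise OtuTableError("replicate_noise must be >= 0")
        total = sum(self.phylum_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise OtuTableError(
                f"phylum_mixture must sum to 1 (got {total!r})")
        if any(w < 0 for w in self.phylum_mixture.values()):
            raise OtuTableError("phylum_mixture weights must be non-negative")


@dataclass
class SyntheticDataset:
    """Observable data plus the ground truth that generated it."""

    table: OtuTable
    design: ReplicateDesign
    taxonomy: TaxonomyTable
    specimen_profiles: pd.DataFrame  # core OTUs x specimens, true rel. abund.
    spurious_by_sample: dict[str, set[str]]
    config: SimulationConfig


def _allocate_phyla(n_otus: int, mixture: dict[str, float], rng) -> list[str]:
    """Largest-remainder allocation of OTU slots to phyla, shuffled.

    Every phylum with positive weight gets at least one OTU so the
    taxonomy covers the full mixture even at small community sizes.
    """
    names = [p for p, w in mixture.items() if w > 0]
    weights = np.array([mixture[p] for p in names])
    ideal = weights / weights.sum() * n_otus
    base = np.maximum(np.floor(ideal).astype(int), 1)
    while base.sum() > n_otus:  # tiny communities: trim the largest group
        base[np.argmax(base)] -= 1
    remainder = ideal - base
    for i in np.argsort(remainder)[::-1][: n_otus - base.sum()]:
        base[i] += 1
    labels = [name for name, k in zip(names, base) for _ in range(k)]
    rng.shuffle(labels)
    return labels


def _core_community(config: SimulationConfig, rng) -> tuple[np.ndarray, list[str]]:
    """Global core profile: lognormal abundances rescaled so each
    phylum's total mass equals its mixture weight."""
    raw = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma,
                        size=config.n_core_otus)
    phyla = _allocate_phyla(config.n_core_otus, config.phylum_mixture, rng)
    profile = np.empty_like(raw)
    arr = np.array(phyla)
    present = {p: config.phylum_mixture[p] for p in set(phyla)}
    norm = sum(present.values())
    for phylum, weight in present.items():
        mask = arr == phylum
        profile[mask] = raw[mask] / raw[mask].sum() * (weight / norm)
    profile /= profile.sum()
    return profile, phyla


def generate(config: SimulationConfig | None = None,
             seed: int | None = None) -> SyntheticDataset:
    """Generate a synthetic triplicate dataset.

    The same config and seed always produce bit-identical output.
    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    core_profile, core_phyla = _core_community(config, rng)
    n_core = config.n_core_otus
    core_ids = [f"Otu{i + 1:04d}" for i in range(n_core)]
    pool_ids = [f"Spur{i + 1:05d}" for i in range(config.spurious_pool_size)]

    # per-specimen true profiles: Dirichlet perturbation of the core
    specimens = [f"Ind{i + 1:02d}" for i in range(config.n_specimens)]
    alpha = np.maximum(config.individuality * core_profile, 1e-9)
    profiles = {}
    for spec in specimens:
        profiles[spec] = rng.dirichlet(alpha)
    profile_df = pd.DataFrame(profiles, index=core_ids)

    sample_ids: list[str] = []
    design_map: dict[str, str] = {}
    core_counts: list[np.ndarray] = []
    spurious_cols: list[dict[int, int]] = []
    spurious_by_sample: dict[str, set[str]] = {}
    geom_p = 1.0 / config.spurious_copy_mean
    # depth varies mostly between specimens (library prep/pooling batch);
    # replicates of one specimen are sequenced at correlated depths
    between_sd = float(np.sqrt(max(
        config.depth_sd ** 2 - config.depth_within_sd ** 2, 0.0)))
    for spec in specimens:
        p = profile_df[spec].to_numpy()
        spec_depth = rng.normal(config.depth_mean, between_sd)
        for r in range(config.replicates_per_specimen):
            sample = f"{spec}_r{r + 1}"
            sample_ids.append(sample)
            design_map[sample] = spec
            depth = int(np.clip(round(rng.normal(spec_depth,
                                                 config.depth_within_sd)),
                                config.depth_min, config.depth_max))
            if config.replicate_noise > 0:
                noisy = p * rng.lognormal(0.0, config.replicate_noise,
                                          size=p.size)
                noisy /= noisy.sum()
            else:
                noisy = p
            core_counts.append(rng.multinomial(depth, noisy))
            k = rng.poisson(config.spurious_rate)
            k = min(k, config.spurious_pool_size)
            chosen = rng.choice(config.spurious_pool_size, size=k,
                                replace=False)
            copies = _spurious_copies(rng, k, geom_p,
                                      config.spurious_high_fraction)
            spurious_cols.append({int(i): int(c)
                                  for i, c in zip(chosen, copies)})
            spurious_by_sample[sample] = {pool_ids[i] for i in chosen}

    # keep only pool members that actually received reads, in pool order
    used = sorted({i for col in spurious_cols for i in col})
    used_ids = [pool_ids[i] for i in used]
    spur_matrix = np.zeros((len(used), len(sample_ids)), dtype=np.int64)
    pos = {i: row for row, i in enumerate(used)}
    for j, col in enumerate(spurious_cols):
        for i, c in col.items():
            spur_matrix[pos[i], j] = c

    counts = np.vstack([np.array(core_counts, dtype=np.int64).T, spur_matrix])
    table = OtuTable(counts, otu_ids=core_ids + used_ids,
                     sample_ids=sample_ids)

    spur_phyla = _phyla_for_pool(used, config, seed)
    lineages = {otu: ("Bacteria", ph) for otu, ph in zip(core_ids, core_phyla)}
    lineages.update({otu: ("Bacteria", ph)
                     for otu, ph in zip(used_ids, spur_phyla)})
    taxonomy = TaxonomyTable(lineages)

    return SyntheticDataset(
        table=table,
        design=ReplicateDesign(design_map),
        taxonomy=taxonomy,
        specimen_profiles=profile_df,
        spurious_by_sample=spurious_by_sample,
        config=config,
    )


def _spurious_copies(rng, k: int, geom_p: float,
                     high_fraction: float) -> np.ndarray:
    """Copy numbers for k spurious OTUs: geometric low-copy noise with a
    small high-copy (>= 10 copies) artifact component."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    copies = rng.geometric(geom_p, size=k).astype(np.int64)
    if high_fraction > 0:
        high = rng.random(k) < high_fraction
        copies[high] = 10 + rng.geometric(0.2, size=int(high.sum()))
    return copies


def _phyla_for_pool(used: list[int], config: SimulationConfig,
                    seed: int | None) -> list[str]:
    """Phylum labels for spurious pool members, stable across which
    members happen to be drawn (a dedicated stream keyed off the seed)."""
    rng = np.random.default_rng(None if seed is None
                                else (int(seed) + 0x5AFE) % (2 ** 31))
    names = list(config.phylum_mixture)
    weights = np.array(list(config.phylum_mixture.values()), dtype=float)
    weights /= weights.sum()
    all_labels = rng.choice(names, size=config.spurious_pool_size, p=weights)
    return [str(all_labels[i]) for i in used]


def calibration_report(dataset: SyntheticDataset) -> dict[str, float]:
    """Descriptive statistics of a synthetic dataset, for comparison
    with the emulation targets.

    Reports the mean number of detected OTUs per sample, mean sequencing
    depth, the mean share of reads carried by OTUs above 1% within-sample
    relative abundance, and the fraction of union-detected OTUs per
    specimen found in only one replicate.
    """
    from .reliability import replicate_agreement  # local import, no cycle

    table = dataset.table
    counts = table.counts
    depths = counts.sum(axis=0)
    detected = (counts >= 1).sum(axis=0)
    rel = counts / depths
    share_top = np.array([
        rel[rel[:, j] > 0.01, j].sum() for j in range(table.n_samples)
    ])
    report = replicate_agreement(table, dataset.design)
    return {
        "mean_otus_per_sample": float(detected.mean()),
        "mean_depth": float(depths.mean()),
        "sd_depth": float(depths.std(ddof=1)),
        "mean_share_reads_above_1pct": float(share_top.mean()),
        "pct_in_three_replicates": report.mean[0],
        "pct_replicate_unique": report.mean[2],
        "n_samples": float(table.n_samples),
    }


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write a dataset as .shared + design TSV + taxonomy TSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "shared": outdir / "synthetic.shared",
        "design": outdir / "design.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.json",
    }
    write_shared(dataset.table, paths["shared"])
    write_design(dataset.design, paths["design"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    truth = {
        "specimen_profiles": {
            spec: dataset.specimen_profiles[spec].round(12).to_dict()
            for spec in dataset.specimen_profiles.columns
        },
        "spurious_by_sample": {
            s: sorted(v) for s, v in dataset.spurious_by_sample.items()
        },
        "config": {k: v for k, v in asdict(dataset.config).items()},
    }
    with paths["truth"].open("w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
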