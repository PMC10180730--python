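"""GREAT-style region-gene association by distance to the nearest TSS.

Each region is anchored at its midpoint and assigned to the single nearest
gene TSS within 1 Mb; assignments are binned by orientation (upstream /
downstream of the TSS relative to the gene's strand) and absolute distance
into 0-5 kb, 5-50 kb, 50-500 kb and >500 kb. Bin occupancies of a region
set are compared against a background of randomly sampled measured CpGs
with a Pearson chi-square (1 df, no continuity correction) per bin, the
test behind TSS-proximal depletion / distal enrichment statements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GeneAnnotation, MethylationDataset
from .regulatory import midpoint

MAX_TSS_DISTANCE = 1_000_000
DISTANCE_BINS = (
    ("0-5 kb", 0, 5_000),
    ("5-50 kb", 5_000, 50_000),
    ("50-500 kb", 50_000, 500_000),
    (">500 kb", 500_000, MAX_TSS_DISTANCE + 1),
)
BIN_LABELS = tuple(label for label, _, _ in DISTANCE_BINS)
NONE_LABEL = "none-within-1Mb"


def distance_bin(distance: int | float) -> str:
    """Bin label for an absolute TSS distance (bins half-open on the right).

    Distances beyond 1 Mb are out of range for an assigned region.
    """
    d = abs(distance)
    if d > MAX_TSS_DISTANCE:
        raise ValueError(f"distance {d} exceeds {MAX_TSS_DISTANCE}")
    for label, lo, hi in DISTANCE_BINS:
        if lo <= d < hi:
            return label
    raise AssertionError("unreachable")


def nearest_tss(chrom: str, start: int, end: int, annotation: GeneAnnotation,
                max_distance: int = MAX_TSS_DISTANCE):
    """Single nearest gene TSS within `max_distance` of the region midpoint.

    Returns (gene_id, signed_distance, orientation) or None. Signed
    distance is positive downstream of the TSS in the gene's reading
    direction and negative upstream; a midpoint exactly at the TSS has
    distance 0 (reported downstream). Ties at equal |distance| prefer the
    gene for which the region lies upstream, then the lower TSS coordinate.
    """
    index = annotation.tss_index()
    if chrom not in index:
        return None
    positions, gene_ids, strands = index[chrom]
    anchor = midpoint(start, end)
    i = int(np.searchsorted(positions, anchor))

    candidates = []
    for j in (i - 1, i):
        if 0 <= j < len(positions):
            candidates.append(j)
    # absorb ties among equal TSS coordinates
    best_dist = min(abs(int(positions[j]) - anchor) for j in candidates) if candidates else None
    if best_dist is None or best_dist > max_distance:
        return None
    tied = [j for j in candidates if abs(int(positions[j]) - anchor) == best_dist]
    # include any additional TSSs at the exact same coordinates
    for j in range(min(tied) - 1, -1, -1):
        if abs(int(positions[j]) - anchor) == best_dist:
            tied.append(j)
        else:
            break
    for j in range(max(tied) + 1, len(positions)):
        if abs(int(positions[j]) - anchor) == best_dist:
            tied.append(j)
        else:
            break

    def signed(j: int) -> int:
        offset = anchor - int(positions[j])
        return offset if strands[j] == "+" else -offset

    def sort_key(j: int):
        upstream = signed(j) < 0
        return (0 if upstream else 1, int(positions[j]), gene_ids[j])

    best = min(tied, key=sort_key)
    sd = signed(best)
    orientation = "upstream" if sd < 0 else "downstream"
    return gene_ids[best], int(sd), orientation


def assign_regions(regions: pd.DataFrame, annotation: GeneAnnotation,
                   max_distance: int = MAX_TSS_DISTANCE) -> pd.DataFrame:
    """Nearest-TSS assignment table for a frame of regions.

    `regions` needs chrom/start/end (and optionally name). Output columns:
    region, gene_id, distance (signed), orientation, bin (NONE_LABEL when no
    TSS lies within `max_distance`).
    """
    records = []
    names = regions["name"] if "name" in regions.columns else pd.Series(
        [f"region_{i}" for i in range(len(regions))]
    )
    for name, row in zip(names, regions.itertuples(index=False)):
        hit = nearest_tss(row.chrom, int(row.start), int(row.end), annotation, max_distance)
        if hit is None:
            records.append((name, None, np.nan, "", NONE_LABEL))
        else:
            gene_id, sd, orientation = hit
            records.append((name, gene_id, sd, orientation, distance_bin(sd)))
    return pd.DataFrame(records, columns=["region", "gene_id", "distance", "orientation", "bin"])


def bin_distances(assignments: pd.DataFrame) -> pd.DataFrame:
    """Orientation x bin summary counts (plus the unassigned row).

    Percentages are of all regions; rows partition the region set.
    """
    total = len(assignments)
    rows = []
    for orientation in ("upstream", "downstream"):
        for label in BIN_LABELS:
            count = int(
                ((assignments["orientation"] == orientation)
                 & (assignments["bin"] == label)).sum()
            )
            rows.append((orientation, label, count))
    rows.append(("none", NONE_LABEL, int((assignments["bin"] == NONE_LABEL).sum())))
    out = pd.DataFrame(rows, columns=["orientation", "bin", "count"])
    out["percent"] = 100.0 * out["count"] / total if total else np.nan
    return out


@dataclass
class BackgroundCpGSet:
    """A seeded without-replacement sample of measured CpG positions."""

    positions: pd.DataFrame  # chrom, pos
    sampling_fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.positions)

    def as_regions(self) -> pd.DataFrame:
        """Background CpGs as 2 bp regions for distance assignment."""
        return pd.DataFrame(
            {
                "chrom": self.positions["chrom"].to_numpy(),
                "start": self.positions["pos"].to_numpy(),
                "end": self.positions["pos"].to_numpy() + 2,
                "name": [f"bg_{i}" for i in range(len(self.positions))],
            }
        )


def sample_background(dataset: MethylationDataset, fraction: float = 0.02,
                      seed: int = 0) -> BackgroundCpGSet:
    """Sample floor(fraction * N) distinct measured CpGs uniformly."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(dataset.sites)
    if n == 0:
        raise ValueError("dataset has no measured CpGs")
    k = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return BackgroundCpGSet(
        positions=dataset.sites.iloc[idx].reset_index(drop=True),
        sampling_fraction=fraction,
        seed=seed,
    )


@dataclass
class ChisqBinResult:
    chi2: float
    p_value: float
    direction: str | None  # "enriched" | "depleted" | None when undefined
    undefined: bool = False


def chisq_bin_test(n_fore: int, k_fore: int, n_back: int, k_back: int) -> ChisqBinResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    The table is [[k_fore, n_fore - k_fore], [k_back, n_back - k_back]].
    A zero row or column margin makes the statistic undefined (flagged,
    not raised). Direction is depleted iff the foreground in-bin proportion
    is below the background proportion.
    """
    if n_fore <= 0 or n_back <= 0:
        raise ValueError("n_fore and n_back must be positive")
    if not (0 <= k_fore <= n_fore and 0 <= k_back <= n_back):
        raise ValueError("k out of range")
    table = np.array(
        [[k_fore, n_fore - k_fore], [k_back, n_back - k_back]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ChisqBinResult(float("nan"), float("nan"), None, undefined=True)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    direction = "depleted" if k_fore / n_fore < k_back / n_back else "enriched"
    return ChisqBinResult(chi2, p, direction)


def compare_to_background(fore_assignments: pd.DataFrame,
                          back_assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-bin chi-square of foreground vs background occupancy.

    Bins pool both orientations (distance-only occupancy, as in depletion /
    enrichment statements about the 0-5 kb TSS bin).
    """
    n_fore, n_back = len(fore_assignments), len(back_assignments)
    rows = []
    for label in BIN_LABELS:
        k_fore = int((fore_assignments["bin"] == label).sum())
        k_back = int((back_assignments["bin"] == label).sum())
        res = chisq_bin_test(n_fore, k_fore, n_back, k_back)
        rows.append(
            {
                "bin": label,
                "k_fore": k_fore,
                "n_fore": n_fore,
                "k_back": k_back,
                "n_back": n_back,
                "chi2": res.chi2,
                "p_value": res.p_value,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows)


def genes_within_window(regions: pd.DataFrame, annotation: GeneAnnotation,
                        window: int = 10_000) -> list[str]:
    """Distinct nearest genes whose TSS is within `window` of a region midpoint."""
    assignments = assign_regions(regions, annotation, max_distance=window)
    hits = assignments.dropna(subset=["distance"])
    return sorted(set(hits["gene_id"]))
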