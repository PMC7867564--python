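"""Bin-based ChIP-seq differential-region identification.

The genome is tiled with 500-nt consecutive non-overlapping bins; tag
5' positions (shifted by half the estimated fragment length toward the
fragment centre) are counted per bin, scaled to a common library size,
stabilised with 30 pseudo-counts and log2-transformed for MA-style
diagnostics.  Each ChIP sample is compared with its matched INPUT
through a one-sided binomial enrichment test per bin (expected ChIP
proportion = library-size ratio), with Benjamini–Hochberg adjustment
across all bins of the phase; adjusted p < 0.05 calls a bin
significant.  The whole procedure is repeated with bins shifted by half
a bin (250 nt) to avoid border effects; a sample's significant
intervals are the union over the two phases.  Bins significant in both
biological replicates of a condition are retained, the retained bins of
all conditions are pooled, and bins separated by less than 500 nt are
merged into continuous regions.  Per-region tag densities, normalised
by region width and library size, are exported for downstream
clustering.

Coordinates are 0-based half-open throughout; tags come and go as BED6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Interval = Tuple[str, int, int]  # chrom, start, end (half-open)

DEFAULT_BIN_SIZE = 500
DEFAULT_PSEUDOCOUNT = 30.0
DEFAULT_SCALE_TO = 1e7  # counts-per-10-million library scaling
DEFAULT_FDR = 0.05


# ---------------------------------------------------------------------
# tag tracks


@dataclass
class TagTrack:
    """Single-end tag alignments of one sample (5' positions + strand)."""

    sample_id: str
    role: str  # "chip" | "input"
    chrom_sizes: Mapping[str, int]
    positions: Mapping[str, np.ndarray]   # chrom -> 5' positions (int64)
    is_plus: Mapping[str, np.ndarray]     # chrom -> strand flags (bool)
    fragment_length: Optional[int] = None

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"tags on undeclared chromosome {chrom!r}")
            if len(pos) and (pos.min() < 0 or pos.max() >= self.chrom_sizes[chrom]):
                raise ValueError(f"tag positions outside {chrom!r} bounds")
            if len(pos) != len(self.is_plus[chrom]):
                raise ValueError(f"position/strand length mismatch on {chrom!r}")

    @property
    def total_tags(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def shifted_positions(self, fragment_length: Optional[int] = None) -> Dict[str, np.ndarray]:
        """5' positions moved by fragment_length/2 toward the fragment
        centre (3'-ward on each strand), clipped to the chromosome."""
        fl = fragment_length if fragment_length is not None else (self.fragment_length or 0)
        half = fl // 2
        out = {}
        for chrom, pos in self.positions.items():
            shift = np.where(self.is_plus[chrom], half, -half)
            out[chrom] = np.clip(pos + shift, 0, self.chrom_sizes[chrom] - 1)
        return out

    @classmethod
    def from_bed(cls, path, chrom_sizes: Mapping[str, int], sample_id: str = "",
                 role: str = "chip") -> "TagTrack":
        """Read BED6 tags: the 5' position is `start` on '+' and
        `end - 1` on '-'."""
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        )
        positions, is_plus = {}, {}
        for chrom, sub in df.groupby("chrom", sort=True):
            plus = (sub["strand"] == "+").to_numpy()
            pos = np.where(plus, sub["start"].to_numpy(), sub["end"].to_numpy() - 1)
            positions[chrom] = pos.astype(np.int64)
            is_plus[chrom] = plus
        return cls(sample_id=sample_id or str(path), role=role,
                   chrom_sizes=chrom_sizes, positions=positions, is_plus=is_plus)

    def to_bed(self, path) -> None:
        """Write each tag as a 1-bp BED6 interval at its 5' position."""
        with open(path, "w") as fh:
            for chrom in sorted(self.positions):
                pos, plus = self.positions[chrom], self.is_plus[chrom]
                for p, pl in zip(pos, plus):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t{'+' if pl else '-'}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


# ---------------------------------------------------------------------
# fragment-length estimation


def estimate_fragment_length(
    track: TagTrack,
    max_shift: int = 400,
    step: int = 5,
    min_corr: float = 0.05,
) -> int:
    """Cross-correlate plus- and minus-strand 5' tag profiles.

    Profiles are binned at ``step`` bp; the Pearson correlation is
    computed for candidate shifts 0..max_shift (multiples of ``step``)
    and the argmax is returned (ties -> smallest shift).  On data with
    no strand structure the estimate is unreliable; a warning is
    emitted when the peak correlation falls below ``min_corr``.
    """
    profiles = []
    n_plus = n_minus = 0
    for chrom, pos in track.positions.items():
        plus = track.is_plus[chrom]
        n_plus += int(plus.sum())
        n_minus += int((~plus).sum())
        nbins = track.chrom_sizes[chrom] // step + 1
        p = np.bincount(pos[plus] // step, minlength=nbins).astype(float)
        m = np.bincount(pos[~plus] // step, minlength=nbins).astype(float)
        profiles.append((p, m))
    if n_plus == 0 or n_minus == 0:
        raise ValueError("fragment-length estimation needs tags on both strands")

    shifts = list(range(0, max_shift + 1, step))
    corrs = []
    for d in shifts:
        k = d // step
        sx = sy = sxx = syy = sxy = n = 0.0
        for p, m in profiles:
            if k >= len(p):
                continue
            x = p[: len(p) - k] if k else p
            y = m[k:]
            sx += x.sum(); sy += y.sum()
            sxx += (x * x).sum(); syy += (y * y).sum()
            sxy += (x * y).sum(); n += x.size
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        corrs.append((sxy - sx * sy / n) / np.sqrt(vx * vy) if vx > 0 and vy > 0 else 0.0)
    corrs = np.asarray(corrs)
    best = int(np.argmax(corrs))  # ties -> smallest shift
    if corrs[best] < min_corr:
        warnings.warn(
            f"weak strand cross-correlation (peak r={corrs[best]:.3f}); "
            "fragment-length estimate is unreliable",
            stacklevel=2,
        )
    return shifts[best]


# ---------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class BinTrack:
    """Per-bin tag counts of one sample on one bin phase.

    Bin j covers [offset + j*bin_size, offset + (j+1)*bin_size)
    intersected with the chromosome; with a nonzero phase offset the
    first (j = -1) and last bins are partial.
    """

    sample_id: str
    bin_size: int
    offset: int
    total_tags: int
    counts: Mapping[str, np.ndarray]
    chrom_sizes: Mapping[str, int]
    scale_to: float = DEFAULT_SCALE_TO
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def first_index(self, chrom: str) -> int:
        return -1 if self.offset > 0 else 0

    def bin_bounds(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """Clipped (starts, ends) of this chromosome's bins."""
        j0 = self.first_index(chrom)
        n = len(self.counts[chrom])
        js = np.arange(j0, j0 + n)
        starts = np.maximum(self.offset + js * self.bin_size, 0)
        ends = np.minimum(self.offset + (js + 1) * self.bin_size, self.chrom_sizes[chrom])
        return starts, ends

    def scaled(self, chrom: str) -> np.ndarray:
        """log2(count · scale_to/total + pseudocount) — the MA-plot scale."""
        return np.log2(
            self.counts[chrom] * (self.scale_to / max(self.total_tags, 1)) + self.pseudocount
        )

    def same_grid(self, other: "BinTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.offset == other.offset
            and set(self.counts) == set(other.counts)
            and all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)
        )


def bin_and_scale(
    track: TagTrack,
    bin_size: int = DEFAULT_BIN_SIZE,
    offset: int = 0,
    fragment_length: Optional[int] = None,
    scale_to: float = DEFAULT_SCALE_TO,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BinTrack:
    """Count centre-shifted tags in consecutive non-overlapping bins."""
    if not 0 <= offset < bin_size:
        raise ValueError("offset must be in [0, bin_size)")
    shifted = track.shifted_positions(fragment_length)
    counts = {}
    for chrom, size in track.chrom_sizes.items():
        j0 = -1 if offset > 0 else 0
        nbins = (size - 1 - offset) // bin_size - j0 + 1
        pos = shifted.get(chrom, np.empty(0, dtype=np.int64))
        idx = (pos - offset) // bin_size - j0
        counts[chrom] = np.bincount(idx, minlength=nbins)
    return BinTrack(
        sample_id=track.sample_id, bin_size=bin_size, offset=offset,
        total_tags=track.total_tags, counts=counts, chrom_sizes=dict(track.chrom_sizes),
        scale_to=scale_to, pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------
# per-bin enrichment


def significant_bins(
    chip: BinTrack,
    input_: BinTrack,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-bin ChIP-vs-INPUT enrichment on one phase.

    The test is a one-sided binomial: conditional on n = chip + input
    tags in a bin, the chip count is Binomial(n, p0) under no
    enrichment, with p0 the chip library fraction.  BH adjustment runs
    across all bins of the phase.  Returns a table with counts, the
    log2-scaled M/A values, p, q and the significance call.
    """
    if not chip.same_grid(input_):
        raise ValueError("chip and input bin grids differ")
    frames = []
    for chrom in sorted(chip.counts):
        starts, ends = chip.bin_bounds(chrom)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "chip": chip.counts[chrom],
            "input": input_.counts[chrom],
            "M": chip.scaled(chrom) - input_.scaled(chrom),
            "A": 0.5 * (chip.scaled(chrom) + input_.scaled(chrom)),
        }))
    table = pd.concat(frames, ignore_index=True)
    n = (table["chip"] + table["input"]).to_numpy()
    x = table["chip"].to_numpy()
    p0 = chip.total_tags / max(chip.total_tags + input_.total_tags, 1)
    pvals = stats.binom.sf(x - 1, n, p0)  # P[X >= x]; n = 0 gives 1
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    table["p"] = pvals
    table["q"] = qvals
    table["significant"] = qvals < fdr
    return table


def significant_intervals(table: pd.DataFrame) -> List[Interval]:
    sig = table[table["significant"]]
    return [(r.chrom, int(r.start), int(r.end)) for r in sig.itertuples()]


# ---------------------------------------------------------------------
# interval algebra (0-based half-open)


def merge_intervals(intervals: Iterable[Interval], max_gap: int = 1) -> List[Interval]:
    """Merge intervals whose gap is < max_gap (max_gap=1 is plain union
    of overlapping/adjacent intervals)."""
    out: List[Interval] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start - out[-1][2] < max_gap:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in merge_intervals(a):
        by_chrom.setdefault(chrom, []).append((s, e))
    out: List[Interval] = []
    for chrom, s, e in merge_intervals(b):
        for s2, e2 in by_chrom.get(chrom, ()):
            lo, hi = max(s, s2), min(e, e2)
            if lo < hi:
                out.append((chrom, lo, hi))
    return sorted(out)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for _, s, e in merge_intervals(intervals))


def interval_jaccard(a: Iterable[Interval], b: Iterable[Interval]) -> float:
    """Base-pair Jaccard index between two interval sets."""
    a, b = merge_intervals(a), merge_intervals(b)
    inter = total_length(intersect_intervals(a, b))
    union = total_length(a) + total_length(b) - inter
    return inter / union if union else 1.0


# ---------------------------------------------------------------------
# consensus regions


@dataclass(frozen=True)
class RegionSet:
    """Sorted, non-overlapping significant regions."""

    regions: Tuple[Interval, ...]

    def __post_init__(self):
        merged = merge_intervals(self.regions)
        if list(self.regions) != merged:
            raise ValueError("regions must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions, columns=["chrom", "start", "end"])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, s, e) in enumerate(self.regions):
                fh.write(f"{chrom}\t{s}\t{e}\tregion_{i}\n")

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    fields = line.split("\t")
                    ivs.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(regions=tuple(merge_intervals(ivs)))


def sample_significant_intervals(
    chip: TagTrack,
    input_: TagTrack,
    bin_size: int = DEFAULT_BIN_SIZE,
    fdr: float = DEFAULT_FDR,
    scale_to: float = DEFAULT_SCALE_TO,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fragment_length: Optional[int] = None,
) -> List[Interval]:
    """Significant bin intervals of one ChIP/INPUT pair, as the union
    over the two half-bin-shifted phases."""
    fl = fragment_length if fragment_length is not None else chip.fragment_length
    ivs: List[Interval] = []
    for offset in (0, bin_size // 2):
        cb = bin_and_scale(chip, bin_size, offset, fl, scale_to, pseudocount)
        ib = bin_and_scale(input_, bin_size, offset, fl, scale_to, pseudocount)
        ivs.extend(significant_intervals(significant_bins(cb, ib, fdr)))
    return merge_intervals(ivs)


def consensus_and_merge(
    per_sample: Mapping[str, Sequence[Interval]],
    condition_of: Mapping[str, str],
    merge_gap: int = DEFAULT_BIN_SIZE,
) -> RegionSet:
    """Replicate-consensus regions: within each condition keep only
    intervals significant in every replicate, pool conditions, and merge
    pieces separated by less than ``merge_gap`` nt."""
    by_cond: Dict[str, List[str]] = {}
    for sample in sorted(per_sample):
        by_cond.setdefault(condition_of[sample], []).append(sample)
    pooled: List[Interval] = []
    for cond in sorted(by_cond):
        samples = by_cond[cond]
        consensus = merge_intervals(per_sample[samples[0]])
        for s in samples[1:]:
            consensus = intersect_intervals(consensus, per_sample[s])
        pooled.extend(consensus)
    return RegionSet(regions=tuple(merge_intervals(pooled, max_gap=merge_gap)))


def region_density(
    regions: RegionSet,
    track: TagTrack,
    fragment_length: Optional[int] = None,
    scale: float = 1e9,
) -> np.ndarray:
    """Per-region normalised tag density:
    (tags in region) / (region width) / (total tags) × scale.

    Tags are counted at their centre-shifted positions; the default
    scale constant 1e9 expresses densities as tags per bp per
    10^9 library tags.
    """
    shifted = {c: np.sort(p) for c, p in track.shifted_positions(fragment_length).items()}
    total = max(track.total_tags, 1)
    out = np.zeros(len(regions.regions))
    for i, (chrom, s, e) in enumerate(regions.regions):
        pos = shifted.get(chrom)
        count = 0 if pos is None else np.searchsorted(pos, e) - np.searchsorted(pos, s)
        out[i] = count / (e - s) / total * scale
    return out


# ---------------------------------------------------------------------
# pipeline


def call_regions(
    chip_tracks: Mapping[str, TagTrack],
    input_of: Mapping[str, TagTrack],
    condition_of: Mapping[str, str],
    bin_size: int = DEFAULT_BIN_SIZE,
    fdr: float = DEFAULT_FDR,
    scale_to: float = DEFAULT_SCALE_TO,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_shift: int = 400,
    shift_step: int = 5,
) -> Tuple[RegionSet, pd.DataFrame]:
    """End-to-end region calling over a replicate design.

    Estimates each ChIP sample's fragment length (also applied to its
    matched INPUT), calls significant bins on both phases, takes the
    replicate consensus per condition, merges to regions and returns
    the per-sample normalised density matrix (regions × samples).
    """
    per_sample: Dict[str, List[Interval]] = {}
    frag: Dict[str, int] = {}
    for sample in sorted(chip_tracks):
        chip = chip_tracks[sample]
        fl = chip.fragment_length
        if fl is None:
            fl = estimate_fragment_length(chip, max_shift=max_shift, step=shift_step)
        frag[sample] = fl
        per_sample[sample] = sample_significant_intervals(
            chip, input_of[sample], bin_size=bin_size, fdr=fdr,
            scale_to=scale_to, pseudocount=pseudocount, fragment_length=fl,
        )
    regions = consensus_and_merge(per_sample, condition_of, merge_gap=bin_size)
    dens = {
        sample: region_density(regions, chip_tracks[sample], fragment_length=frag[sample])
        for sample in sorted(chip_tracks)
    }
    density = pd.DataFrame(dens)
    density.insert(0, "chrom", [r[0] for r in regions.regions])
    density.insert(1, "start", [r[1] for r in regions.regions])
    density.insert(2, "end", [r[2] for r in regions.regions])
    return regions, density


def ma_plot(table: pd.DataFrame, path) -> None:
    """Diagnostic MA plot of one phase's bin table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = table["significant"]
    ax.scatter(table.loc[~sig, "A"], table.loc[~sig, "M"], s=2, c="grey", alpha=0.4)
    ax.scatter(table.loc[sig, "A"], table.loc[sig, "M"], s=4, c="crimson")
    ax.set_xlabel("A (mean log2 scaled count)")
    ax.set_ylabel("M (log2 ChIP / INPUT)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
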