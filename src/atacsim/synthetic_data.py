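"""Synthetic ATAC-seq-like parent samples: layout, peaks and fragments.

The generator emulates the statistical structure of real chromatin
accessibility libraries that the rest of the toolkit is designed around,
with three controlled features:

* *peaky signal*: a configurable fraction of fragments (the FrIP score,
  realistic range roughly 0.34-0.72) concentrates in a set of
  non-overlapping peaks whose per-peak intensities are negative-binomial
  distributed, since real peak heights are strongly over-dispersed;
* *inaccessible blocks*: a configurable fraction of the genome carries no
  fragments at all; whole bins inside these blocks are zero in every
  sample derived from the parent, which is exactly what produces co-zero
  bins (a few percent of a binned bivariate distribution) when two tracks
  are compared;
* *ATAC-like fragment lengths*: a Gaussian mixture with nucleosome-free
  (~80 bp), mono-nucleosome (~200 bp) and di-nucleosome (~400 bp)
  components. Lengths are cosmetic for 10 kb overlap binning but matter
  under the containment assignment policy.

The default genome is gigabase-scale on purpose. Under FPKM
standardization with ceiling rounding, the background count per bin sits
below the 1-FPKM threshold - so nearly all non-peak bins quantize to a
constant WFpkm of 1 - precisely when the genome length exceeds roughly
background_fraction x 1 Gb, *independent* of bin size and library size.
Real binned chromatin-accessibility data live in that regime, and the
behaviour of every co-zero-masking effect depends on it; a toy 10 Mb
genome puts background sampling variance into WFpkm and produces
qualitatively wrong statistics. Small configs remain available for
plumbing tests.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .genomic_io import (
    FragmentSet,
    GenomeLayout,
    PeakSet,
    write_chrom_sizes,
    write_fragments_bed,
    write_peaks_narrowpeak,
)

DEFAULT_FRAGMENT_MIXTURE = ((80.0, 25.0, 0.50), (200.0, 35.0, 0.35), (400.0, 60.0, 0.15))


@dataclass(frozen=True)
class ParentConfig:
    """Knobs of one synthetic parent sample.

    ``target_frip`` is the intended fraction of fragments overlapping
    peaks; ``inaccessible_block_fraction`` is the genome fraction covered
    by zero-coverage blocks (disjoint from peaks), the mechanism that
    creates co-zero bins downstream.
    """

    chromosome_lengths: tuple[int, ...] = (1_250_000_000, 1_250_000_000)
    n_peaks: int = 100_000
    peak_width_range: tuple[int, int] = (500, 2000)
    peak_intensity_dispersion: float = 0.15  # negative-binomial shape r
    target_frip: float = 0.50
    inaccessible_block_fraction: float = 0.05
    inaccessible_block_width: int = 150_000
    fragment_length_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_FRAGMENT_MIXTURE
    library_size: int = 2_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_frip < 1:
            raise ValidationError("target_frip must lie in (0, 1)")
        if not 0 <= self.inaccessible_block_fraction < 1:
            raise ValidationError("inaccessible_block_fraction must lie in [0, 1)")
        weights = sum(w for _, _, w in self.fragment_length_mixture)
        if abs(weights - 1.0) > 1e-9:
            raise ValidationError("fragment length mixture weights must sum to 1")
        if self.peak_width_range[0] > self.peak_width_range[1]:
            raise ValidationError("invalid peak width range")
        if self.library_size < 1 or self.n_peaks < 1:
            raise ValidationError("library_size and n_peaks must be positive")

    @property
    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(len(self.chromosome_lengths)))
        return GenomeLayout(names, tuple(self.chromosome_lengths))


def _pack_intervals(
    rng: np.random.Generator, chrom_length: int, widths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Place intervals of the given widths disjointly and in random order
    along one chromosome, with uniformly random gaps."""
    total = int(widths.sum())
    free = chrom_length - total
    if free < 0:
        raise ValidationError("requested intervals do not fit the chromosome")
    k = len(widths)
    if k == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = rng.permutation(k)
    anchors = np.sort(rng.integers(0, free + 1, size=k))
    starts_in_order = anchors + np.concatenate([[0], np.cumsum(widths[order])[:-1]])
    starts = np.empty(k, dtype=np.int64)
    starts[order] = starts_in_order
    return starts, starts + widths


def sample_peak_landscape(config: ParentConfig) -> tuple[GenomeLayout, PeakSet, PeakSet]:
    """Draw the non-overlapping peak set and inaccessible blocks.

    Peaks and blocks are packed together per chromosome so they can never
    overlap; blocks cover approximately ``inaccessible_block_fraction`` of
    the genome. Returns (layout, peaks, blocks) with blocks represented as
    a second PeakSet.
    """
    layout = config.layout
    rng = np.random.default_rng((config.seed, 0))
    genome_bp = sum(layout.lengths)
    n_blocks = max(
        0, int(round(config.inaccessible_block_fraction * genome_bp / config.inaccessible_block_width))
    )
    # allocate peak/block counts per chromosome proportional to length
    props = np.asarray(layout.lengths, dtype=float) / genome_bp
    peak_alloc = rng.multinomial(config.n_peaks, props)
    block_alloc = rng.multinomial(n_blocks, props) if n_blocks else np.zeros(len(props), int)

    peak_chrom, peak_start, peak_end = [], [], []
    block_chrom, block_start, block_end = [], [], []
    for ci, length in enumerate(layout.lengths):
        npk, nbl = int(peak_alloc[ci]), int(block_alloc[ci])
        pw = rng.integers(config.peak_width_range[0], config.peak_width_range[1] + 1, size=npk)
        bw = np.full(nbl, config.inaccessible_block_width, dtype=np.int64)
        widths = np.concatenate([pw, bw]).astype(np.int64)
        starts, ends = _pack_intervals(rng, length, widths)
        peak_chrom += [ci] * npk
        peak_start += starts[:npk].tolist()
        peak_end += ends[:npk].tolist()
        block_chrom += [ci] * nbl
        block_start += starts[npk:].tolist()
        block_end += ends[npk:].tolist()

    peaks = PeakSet(
        layout,
        np.array(peak_chrom, dtype=np.int32),
        np.array(peak_start, dtype=np.int64),
        np.array(peak_end, dtype=np.int64),
    )
    blocks = PeakSet(
        layout,
        np.array(block_chrom, dtype=np.int32),
        np.array(block_start, dtype=np.int64),
        np.array(block_end, dtype=np.int64),
    ) if n_blocks else PeakSet(layout, np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, np.int64))
    return layout, peaks, blocks


def _draw_fragment_lengths(rng: np.random.Generator, config: ParentConfig, n: int) -> np.ndarray:
    means = np.array([m for m, _, _ in config.fragment_length_mixture])
    sds = np.array([s for _, s, _ in config.fragment_length_mixture])
    weights = np.array([w for _, _, w in config.fragment_length_mixture])
    comp = rng.choice(len(means), size=n, p=weights)
    lengths = rng.normal(means[comp], sds[comp])
    return np.maximum(20, lengths.round()).astype(np.int64)


def _clip_to_accessible(
    mid: np.ndarray, start: np.ndarray, end: np.ndarray,
    block_start: np.ndarray, block_end: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate fragments at the nearest block boundary around their midpoint,
    so no fragment base falls inside an inaccessible block."""
    if len(block_start) == 0:
        return start, end
    # midpoints are guaranteed outside blocks; the enclosing accessible
    # interval runs from the previous block end to the next block start
    nxt = np.searchsorted(block_start, mid, side="right")
    prev_end = np.where(nxt > 0, block_end[np.maximum(nxt - 1, 0)], 0)
    prev_end = np.where(mid >= prev_end, prev_end, 0)  # mid before first block
    next_start = np.where(
        nxt < len(block_start), block_start[np.minimum(nxt, len(block_start) - 1)], np.iinfo(np.int64).max
    )
    return np.maximum(start, prev_end), np.minimum(end, next_start)


def sample_fragments(
    layout: GenomeLayout, peaks: PeakSet, blocks: PeakSet, config: ParentConfig
) -> FragmentSet:
    """Draw the parent library: peak-enriched plus uniform background fragments.

    Per-peak fragment counts follow a negative binomial around the mean
    intensity and are allocated by multinomial draw so the peak total is
    exact. The peak/background split is corrected for background fragments
    that land inside peaks, so the realized FrIP tracks ``target_frip``.
    Background midpoints are uniform over the accessible genome; fragments
    are truncated at inaccessible-block boundaries, so blocks stay at
    exactly zero coverage.
    """
    rng = np.random.default_rng((config.seed, 1))
    lib = config.library_size
    genome_bp = sum(layout.lengths)
    block_bp = int((blocks.end - blocks.start).sum()) if len(blocks) else 0
    peak_bp = int((peaks.end - peaks.start).sum())
    accessible_bp = genome_bp - block_bp
    # fraction of background fragments expected to land inside peaks
    q = peak_bp / accessible_bp
    n_peak_frags = int(round(lib * max(0.0, (config.target_frip - q)) / (1.0 - q)))
    if n_peak_frags > lib:
        raise ValidationError("target FrIP infeasible for this library size")
    n_bg = lib - n_peak_frags

    # ---- peak fragments ---------------------------------------------------
    n_peaks = len(peaks)
    mean_intensity = max(n_peak_frags / n_peaks, 1e-9)
    r = config.peak_intensity_dispersion
    nb = rng.negative_binomial(r, r / (r + mean_intensity), size=n_peaks).astype(float)
    if nb.sum() == 0:
        nb[:] = 1.0
    counts = rng.multinomial(n_peak_frags, nb / nb.sum())
    peak_ids = np.repeat(np.arange(n_peaks), counts)
    widths = (peaks.end - peaks.start)[peak_ids]
    centers = (peaks.start + peaks.end)[peak_ids] // 2
    mids = centers + rng.normal(0, widths / 5.0).round().astype(np.int64)
    mids = np.clip(mids, peaks.start[peak_ids] + 1, peaks.end[peak_ids] - 1)
    peak_chrom = peaks.chrom_idx[peak_ids].astype(np.int32)

    # ---- background fragments ---------------------------------------------
    # uniform midpoints over the accessible genome, per chromosome
    chrom_lengths = np.asarray(layout.lengths, dtype=np.int64)
    acc_per_chrom = chrom_lengths.copy()
    for ci in range(layout.n_chromosomes):
        if len(blocks):
            on = blocks.chrom_idx == ci
            acc_per_chrom[ci] -= int((blocks.end[on] - blocks.start[on]).sum())
    bg_alloc = rng.multinomial(n_bg, acc_per_chrom / acc_per_chrom.sum())
    bg_chrom_list, bg_mid_list = [], []
    for ci in range(layout.n_chromosomes):
        n = int(bg_alloc[ci])
        if n == 0:
            continue
        pos = rng.integers(0, acc_per_chrom[ci], size=n)
        if len(blocks):
            on = blocks.chrom_idx == ci
            bs, be = blocks.start[on], blocks.end[on]
            # map accessible coordinates to genome coordinates by shifting
            # past every block that precedes them
            acc_block_start = bs - np.concatenate([[0], np.cumsum(be - bs)[:-1]])
            shift = np.cumsum(be - bs)
            idx = np.searchsorted(acc_block_start, pos, side="right")
            pos = pos + np.where(idx > 0, shift[np.maximum(idx - 1, 0)], 0)
        bg_chrom_list.append(np.full(n, ci, dtype=np.int32))
        bg_mid_list.append(pos.astype(np.int64))
    bg_chrom = np.concatenate(bg_chrom_list) if bg_chrom_list else np.empty(0, np.int32)
    bg_mid = np.concatenate(bg_mid_list) if bg_mid_list else np.empty(0, np.int64)

    chrom = np.concatenate([peak_chrom, bg_chrom])
    mid = np.concatenate([mids, bg_mid])
    lengths = _draw_fragment_lengths(rng, config, len(mid))
    start = mid - lengths // 2
    end = start + lengths
    # clamp to chromosome bounds
    start = np.maximum(start, 0)
    end = np.minimum(end, chrom_lengths[chrom])
    # truncate at block boundaries per chromosome
    for ci in range(layout.n_chromosomes):
        if not len(blocks):
            break
        on_frag = chrom == ci
        on_block = blocks.chrom_idx == ci
        s, e = _clip_to_accessible(
            mid[on_frag], start[on_frag], end[on_frag],
            blocks.start[on_block], blocks.end[on_block],
        )
        start[on_frag], end[on_frag] = s, e
    bad = start >= end
    if np.any(bad):  # degenerate after clipping; re-centre as 20 bp stubs
        start[bad] = np.maximum(mid[bad] - 10, 0)
        end[bad] = start[bad] + 20
    return FragmentSet(layout, chrom, start, end)


def realized_frip(frags: FragmentSet, peaks: PeakSet) -> float:
    """Fraction of fragments overlapping any peak."""
    hits = np.zeros(len(frags), dtype=bool)
    for ci in range(frags.layout.n_chromosomes):
        on_p = peaks.chrom_idx == ci
        ps, pe = peaks.start[on_p], peaks.end[on_p]
        if len(ps) == 0:
            continue
        on_f = frags.chrom_idx == ci
        fs, fe = frags.start[on_f], frags.end[on_f]
        # fragment overlaps a peak iff some peak start < frag end and that
        # peak's end > frag start; peaks are disjoint and sorted
        idx = np.searchsorted(ps, fe, side="left") - 1
        valid = idx >= 0
        ov = np.zeros(len(fs), dtype=bool)
        ov[valid] = pe[idx[valid]] > fs[valid]
        hits[np.nonzero(on_f)[0]] = ov
    return float(hits.mean()) if len(frags) else 0.0


def generate_parent_sample(
    config: ParentConfig, out_prefix: str | Path | None = None
) -> tuple[FragmentSet, PeakSet, GenomeLayout]:
    """Compose landscape + fragments; optionally emit BED3 / narrowPeak /
    chrom.sizes / manifest.json files consumable by the CLI pipeline."""
    layout, peaks, blocks = sample_peak_landscape(config)
    frags = sample_fragments(layout, peaks, blocks, config)
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fragments_bed(frags, f"{prefix}.bed")
        write_peaks_narrowpeak(peaks, f"{prefix}.narrowPeak")
        write_chrom_sizes(layout, f"{prefix}.chrom.sizes")
        manifest = asdict(config)
        manifest["realized_frip"] = realized_frip(frags, peaks)
        manifest["n_fragments"] = frags.library_size
        with open(f"{prefix}.manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return frags, peaks, layout
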