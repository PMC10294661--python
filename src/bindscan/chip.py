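"""Sliding-window ChIP-seq enrichment.

The statistic implemented here turns a per-nucleotide read-depth track into a
local enrichment ratio: the mean depth in a small moving window (default 30 nt,
stepping 15 nt) divided by the mean depth in a large background window (default
3,000 nt) centered on the small one.  Control enrichment is subtracted
element-wise, replicates are averaged window-wise, and contiguous runs of
high-enrichment windows can be merged into candidate bound regions.

Coordinates are 0-based half-open throughout, matching bedGraph.  Replicons are
treated as linear (no wraparound); background windows that fall off either end
are clipped to the replicon and averaged over the clipped extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DepthTrack",
    "EnrichmentTrack",
    "EnrichedRegion",
    "read_depth",
    "windowed_enrichment",
    "subtract_control",
    "average_replicates",
    "call_enriched_windows",
    "write_enrichment",
]


@dataclass
class DepthTrack:
    """Per-nucleotide coverage over a named linear replicon."""

    replicon: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be non-negative")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass
class EnrichmentTrack:
    """Enrichment ratios sampled every ``step`` nucleotides.

    ``values[i]`` is the ratio for the window starting at ``i * step``; ``mask``
    is True where the window is valid (background mean > 0).  Invalid windows
    carry NaN and no numeric meaning.
    """

    replicon: str
    window: int
    step: int
    background: int
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have the same shape")
        if self.window > self.background:
            raise ValueError("window must not exceed background")

    @property
    def n_windows(self) -> int:
        return int(self.values.size)

    def window_start(self, i: int) -> int:
        return i * self.step

    def _check_compatible(self, other: "EnrichmentTrack") -> None:
        for attr in ("replicon", "window", "step", "background", "n_windows"):
            if getattr(self, attr) != getattr(other, attr):
                raise ValueError(
                    f"enrichment tracks differ in {attr}: "
                    f"{getattr(self, attr)!r} vs {getattr(other, attr)!r}"
                )


@dataclass
class EnrichedRegion:
    """A run of consecutive above-threshold windows, merged half-open."""

    start: int
    end: int
    peak_value: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if self.n_windows < 1:
            raise ValueError("region must contain at least one window")


def read_depth(path, format: str = "bedgraph", replicon_length: int | None = None) -> DepthTrack:
    """Read a per-nucleotide depth track from bedGraph or fixed-step wiggle.

    Uncovered positions get depth 0.  Overlapping bedGraph intervals are an
    error, as are intervals extending past ``replicon_length``.
    """
    fmt = format.lower()
    if fmt == "bedgraph":
        return _read_bedgraph(path, replicon_length)
    if fmt in ("wiggle", "wig"):
        return _read_wiggle(path, replicon_length)
    raise ValueError(f"unknown depth format: {format!r}")


def _read_bedgraph(path, replicon_length: int | None) -> DepthTrack:
    intervals: list[tuple[int, int, float]] = []
    replicon = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}: {line!r}")
            chrom, s, e, v = parts
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}: {line!r}") from exc
            if end <= start or start < 0:
                raise ValueError(f"{path}: invalid interval on line {lineno}: {line!r}")
            if replicon is None:
                replicon = chrom
            elif chrom != replicon:
                raise ValueError(f"{path}: multiple replicons in one track (line {lineno})")
            intervals.append((start, end, value))
    if replicon is None:
        replicon = "replicon"
    length = replicon_length
    if length is None:
        length = max((e for _, e, _ in intervals), default=0)
    depth = np.zeros(length, dtype=float)
    covered = np.zeros(length, dtype=bool)
    for start, end, value in intervals:
        if end > length:
            raise ValueError(f"{path}: interval [{start}, {end}) extends past replicon end {length}")
        if covered[start:end].any():
            raise ValueError(f"{path}: overlapping bedGraph intervals at [{start}, {end})")
        covered[start:end] = True
        depth[start:end] = value
    return DepthTrack(replicon, depth)


def _read_wiggle(path, replicon_length: int | None) -> DepthTrack:
    # fixedStep only; wiggle starts are 1-based.
    chunks: list[tuple[int, int, list[float]]] = []  # (start0, span, values)
    replicon = None
    step = span = 1
    pos = None
    values: list[float] = []
    start0 = 0

    def flush():
        if pos is not None:
            chunks.append((start0, span, values.copy()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                flush()
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                try:
                    chrom = fields["chrom"]
                    start0 = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path}: malformed fixedStep header line {lineno}") from exc
                if step != span:
                    raise ValueError(f"{path}: only step == span fixedStep wiggle is supported (line {lineno})")
                if replicon is None:
                    replicon = chrom
                elif chrom != replicon:
                    raise ValueError(f"{path}: multiple replicons in one track (line {lineno})")
                pos = start0
                values = []
            else:
                if pos is None:
                    raise ValueError(f"{path}: data before fixedStep header (line {lineno})")
                try:
                    values.append(float(line))
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed wiggle value line {lineno}: {line!r}") from exc
    flush()
    if replicon is None:
        replicon = "replicon"
    end = max((s + span * len(v) for s, span, v in chunks), default=0)
    length = replicon_length if replicon_length is not None else end
    if end > length:
        raise ValueError(f"{path}: wiggle data extend past replicon end {length}")
    depth = np.zeros(length, dtype=float)
    for s, sp, vals in chunks:
        for i, v in enumerate(vals):
            depth[s + i * sp : s + (i + 1) * sp] = v
    return DepthTrack(replicon, depth)


def windowed_enrichment(
    track: DepthTrack, window: int = 30, step: int = 15, background: int = 3000
) -> EnrichmentTrack:
    """Local enrichment: small-window mean depth over centered background mean.

    The value for the window starting at ``s`` is
    ``mean(depth[s : s+window]) / mean(depth[bg_lo : bg_hi])`` where the
    background window of ``background`` nt is centered on the small window and
    clipped to the replicon.  Windows whose background mean is zero are masked.
    The ratio is invariant to rescaling the whole track, so libraries of
    different sequencing depth are directly comparable.
    """
    if window <= 0 or step <= 0 or background <= 0:
        raise ValueError("window, step and background must be positive")
    if window > background:
        raise ValueError("window must not exceed background")
    n = track.length
    if n < window:
        raise ValueError(f"track length {n} is shorter than window {window}")

    csum = np.concatenate([[0.0], np.cumsum(track.depth)])
    n_windows = (n - window) // step + 1
    starts = np.arange(n_windows) * step

    win_mean = (csum[starts + window] - csum[starts]) / window

    bg_lo = starts + (window - background) // 2
    bg_hi = bg_lo + background
    bg_lo = np.clip(bg_lo, 0, n)
    bg_hi = np.clip(bg_hi, 0, n)
    bg_len = bg_hi - bg_lo
    bg_mean = (csum[bg_hi] - csum[bg_lo]) / bg_len

    mask = bg_mean > 0
    values = np.full(n_windows, np.nan)
    values[mask] = win_mean[mask] / bg_mean[mask]
    return EnrichmentTrack(track.replicon, window, step, background, values, mask)


def subtract_control(sample: EnrichmentTrack, control: EnrichmentTrack) -> EnrichmentTrack:
    """Element-wise sample − control; masks propagate from either input."""
    sample._check_compatible(control)
    mask = sample.mask & control.mask
    values = np.full_like(sample.values, np.nan)
    values[mask] = sample.values[mask] - control.values[mask]
    return EnrichmentTrack(
        sample.replicon, sample.window, sample.step, sample.background, values, mask
    )


def average_replicates(tracks: list[EnrichmentTrack]) -> EnrichmentTrack:
    """Per-window mean over replicate tracks, ignoring masked entries.

    A window is masked in the output only if it is masked in every input.
    """
    if not tracks:
        raise ValueError("average_replicates requires at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        first._check_compatible(t)
    stack = np.stack([t.values for t in tracks])
    masks = np.stack([t.mask for t in tracks])
    counts = masks.sum(axis=0)
    sums = np.where(masks, stack, 0.0).sum(axis=0)
    mask = counts > 0
    values = np.full(first.n_windows, np.nan)
    values[mask] = sums[mask] / counts[mask]
    return EnrichmentTrack(first.replicon, first.window, first.step, first.background, values, mask)


def call_enriched_windows(
    track: EnrichmentTrack, threshold: float, min_consecutive: int = 2
) -> list[EnrichedRegion]:
    """Merge maximal runs of >= ``min_consecutive`` above-threshold windows.

    A region spans from the first window's start to the last window's end,
    half-open.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hits = track.mask & (track.values >= threshold)
    regions: list[EnrichedRegion] = []
    i = 0
    n = track.n_windows
    while i < n:
        if not hits[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hits[j + 1]:
            j += 1
        run_len = j - i + 1
        if run_len >= min_consecutive:
            start = track.window_start(i)
            end = track.window_start(j) + track.window
            peak = float(np.nanmax(track.values[i : j + 1]))
            regions.append(EnrichedRegion(start, end, peak, run_len))
        i = j + 1
    return regions


def write_enrichment(track: EnrichmentTrack, path) -> None:
    """Write an enrichment track as bedGraph, one ``step``-wide interval per
    unmasked window; masked windows are omitted."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{track.replicon}_enrichment" '
            f"window={track.window} step={track.step} background={track.background}\n"
        )
        for i in range(track.n_windows):
            if not track.mask[i]:
                continue
            s = track.window_start(i)
            fh.write(f"{track.replicon}\t{s}\t{s + track.step}\t{track.values[i]:.6f}\n")
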