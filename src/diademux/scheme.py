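"""Isolation-window scheme construction and demultiplexing regions.

An overlapped DIA acquisition repeats a small number of *cycle variants*:
each variant is one pass of non-overlapping isolation windows, and
successive variants are shifted by a fixed m/z offset.  The shifted window
edges cut the covered m/z range into *demultiplexing regions* — the
smallest intervals to which fragment-ion signal can be assigned from the
pattern of overlapping windows.  For the canonical scheme (twenty 20 Th
windows over 500–900 Th, alternating cycles shifted by −10 Th) the regions
are the 41 half-windows of 10 Th from 490 to 900 Th.

All intervals are half-open ``[low, high)``: an m/z exactly on a shared
edge belongs to the upper window/region, so edges are never double-counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

__all__ = [
    "SchemeError",
    "IsolationWindow",
    "CycleVariant",
    "IsolationScheme",
    "DemuxRegion",
    "build_windows",
    "build_overlap_scheme",
    "compute_demux_regions",
    "regions_in_window",
    "adjust_edges",
    "inclusion_list",
]

# Window edges are compared after rounding to this many decimals so that
# floating-point arithmetic on shifted boundaries never splits one physical
# edge into two regions.
_EDGE_DECIMALS = 6
_EDGE_TOL = 10.0 ** (-_EDGE_DECIMALS)


class SchemeError(ValueError):
    """Invalid isolation-scheme configuration."""


@dataclass(frozen=True, order=True)
class IsolationWindow:
    """Half-open precursor isolation interval ``[low, high)`` in Th."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise SchemeError(
                f"isolation window requires low < high, got [{self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def contains(self, mz: float) -> bool:
        return self.low <= mz < self.high

    def matches(self, other: "IsolationWindow", tol: float = 0.01) -> bool:
        return abs(self.low - other.low) <= tol and abs(self.high - other.high) <= tol


@dataclass(frozen=True)
class DemuxRegion:
    """One demultiplexing region: half-open ``[low, high)``, 0-indexed ascending."""

    low: float
    high: float
    index: int

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, mz: float) -> bool:
        return self.low <= mz < self.high


@dataclass(frozen=True)
class CycleVariant:
    """One pass of non-overlapping isolation windows, sorted ascending."""

    windows: tuple[IsolationWindow, ...]
    variant_id: int

    def __post_init__(self) -> None:
        ws = self.windows
        for a, b in zip(ws, ws[1:]):
            if b.low < a.high - _EDGE_TOL:
                raise SchemeError(
                    f"variant {self.variant_id}: windows [{a.low},{a.high}) and "
                    f"[{b.low},{b.high}) overlap or are unsorted"
                )


@dataclass(frozen=True)
class IsolationScheme:
    """Ordered cycle variants repeated cyclically in acquisition order."""

    variants: tuple[CycleVariant, ...]
    width: float
    offset: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if not self.variants:
            raise SchemeError("scheme requires at least one cycle variant")
        counts = {len(v.windows) for v in self.variants}
        if len(counts) != 1:
            raise SchemeError(f"variants have unequal window counts: {sorted(counts)}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def windows_per_variant(self) -> int:
        return len(self.variants[0].windows)

    def all_windows(self) -> list[IsolationWindow]:
        return [w for v in self.variants for w in v.windows]

    def regions(self) -> list[DemuxRegion]:
        return compute_demux_regions(self)

    def find_window(
        self, window: IsolationWindow, tol: float = 0.01
    ) -> list[tuple[int, int]]:
        """All (variant_id, window position) pairs matching *window* within *tol*."""
        hits = []
        for v in self.variants:
            for pos, w in enumerate(v.windows):
                if w.matches(window, tol):
                    hits.append((v.variant_id, pos))
        return hits


def build_windows(
    range_low: float, range_high: float, width: float
) -> list[IsolationWindow]:
    """Consecutive half-open windows of *width* covering ``[range_low, range_high)``.

    The range must be a positive integer multiple of the window width.
    """
    if width <= 0:
        raise SchemeError(f"window width must be positive, got {width}")
    span = range_high - range_low
    if span <= 0:
        raise SchemeError(
            f"empty m/z range [{range_low}, {range_high}): nothing to cover"
        )
    n = round(span / width)
    remainder = span - n * width
    if n < 1 or abs(remainder) > _EDGE_TOL:
        raise SchemeError(
            f"range {span} Th is not a multiple of window width {width} Th "
            f"(remainder {span - math.floor(span / width) * width:g} Th)"
        )
    return [
        IsolationWindow(
            round(range_low + i * width, _EDGE_DECIMALS),
            round(range_low + (i + 1) * width, _EDGE_DECIMALS),
        )
        for i in range(n)
    ]


def build_overlap_scheme(
    range_low: float, range_high: float, width: float, offset: float
) -> IsolationScheme:
    """Isolation scheme whose cycle variants are shifted copies of one window pass.

    ``offset = 0`` yields a single-variant (non-overlapped) scheme.  Otherwise
    ``|offset|`` must divide the window width evenly; ``width/|offset|``
    variants are generated, variant *k* shifted by ``k * offset``.
    """
    if offset == 0:
        variants = (CycleVariant(tuple(build_windows(range_low, range_high, width)), 0),)
        return IsolationScheme(variants, width, 0.0, range_low, range_high)
    if abs(offset) >= width:
        raise SchemeError(
            f"|offset| {abs(offset)} Th >= window width {width} Th: "
            "shifted windows would not overlap"
        )
    k = round(width / abs(offset))
    if abs(width - k * abs(offset)) > _EDGE_TOL:
        raise SchemeError(
            f"offset {offset} Th does not evenly divide window width {width} Th"
        )
    variants = []
    for v in range(k):
        shift = round(v * offset, _EDGE_DECIMALS)
        windows = tuple(
            build_windows(range_low + shift, range_high + shift, width)
        )
        variants.append(CycleVariant(windows, v))
    return IsolationScheme(tuple(variants), width, offset, range_low, range_high)


def compute_demux_regions(scheme: IsolationScheme) -> list[DemuxRegion]:
    """Regions between consecutive distinct window edges over all variants.

    Only intervals actually covered by at least one window are kept; for the
    default 2-variant scheme this yields 41 regions of 10 Th from 490 to 900.
    """
    edges = sorted(
        {round(e, _EDGE_DECIMALS) for v in scheme.variants for w in v.windows
         for e in (w.low, w.high)}
    )
    windows = scheme.all_windows()
    regions: list[DemuxRegion] = []
    for lo, hi in zip(edges, edges[1:]):
        mid = 0.5 * (lo + hi)
        if any(w.contains(mid) for w in windows):
            regions.append(DemuxRegion(lo, hi, len(regions)))
    return regions


def regions_in_window(
    window: IsolationWindow, regions: Sequence[DemuxRegion]
) -> set[int]:
    """Indices of regions fully contained in *window*.

    A region that straddles a window edge indicates the regions were not
    derived from the scheme containing this window and is an error.
    """
    out: set[int] = set()
    for r in regions:
        inside = r.low >= window.low - _EDGE_TOL and r.high <= window.high + _EDGE_TOL
        overlaps = r.low < window.high - _EDGE_TOL and r.high > window.low + _EDGE_TOL
        if inside:
            out.add(r.index)
        elif overlaps:
            raise SchemeError(
                f"region [{r.low},{r.high}) partially overlaps window "
                f"[{window.low},{window.high}): scheme/regions mismatch"
            )
    return out


def region_of(mz: float, regions: Sequence[DemuxRegion]) -> DemuxRegion:
    """The region containing *mz* (half-open convention)."""
    for r in regions:
        if r.contains(mz):
            return r
    raise SchemeError(f"m/z {mz} lies outside all demultiplexing regions")


def adjust_edges(
    scheme: IsolationScheme,
    penalty: Callable[[float], float],
    search_halfwidth: float = 0.5,
    step: float = 0.05,
) -> IsolationScheme:
    """Optional hook shifting each window edge to a nearby low-penalty m/z.

    *penalty* scores how undesirable placing an edge at a given m/z is (e.g.
    local precursor density); each interior edge moves to the minimizing
    point within ``+/- search_halfwidth``, ties broken toward the nominal
    edge.  Disabled by default throughout the package — nominal edges are
    exact unless this is called explicitly.
    """
    def best(edge: float) -> float:
        n = int(round(search_halfwidth / step))
        candidates = [round(edge + i * step, _EDGE_DECIMALS) for i in range(-n, n + 1)]
        return min(candidates, key=lambda x: (penalty(x), abs(x - edge)))

    new_variants = []
    for v in scheme.variants:
        edges = [v.windows[0].low] + [w.high for w in v.windows]
        moved = [best(e) for e in edges]
        windows = tuple(
            IsolationWindow(a, b) for a, b in zip(moved, moved[1:])
        )
        new_variants.append(CycleVariant(windows, v.variant_id))
    return IsolationScheme(
        tuple(new_variants), scheme.width, scheme.offset,
        scheme.range_low, scheme.range_high,
    )


def inclusion_list(scheme: IsolationScheme) -> list[tuple[int, float, float]]:
    """Instrument-ready (variant_id, center m/z, width) rows, acquisition order."""
    return [
        (v.variant_id, w.center, w.width)
        for v in scheme.variants
        for w in v.windows
    ]
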