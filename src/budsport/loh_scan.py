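"""Run-based detection of loss-of-heterozygosity segments.

A site is LOH-discordant when the wild type is heterozygous (code 1) but the
sport is homozygous (0 or 2).  Concordant-homozygous sites carry no
information about heterozygosity loss and are transparent to the scan; the
informative site classes are:

* ``D`` - LOH-discordant (evidence for the event),
* ``H`` - concordant heterozygous (an interruption: evidence against, or a
  het false negative of the calling pipeline),
* ``R`` - reverse-discordant (wild homozygous, sport heterozygous; a
  gain-of-heterozygosity call that vetoes merging).

The scanner takes maximal runs of consecutive ``D`` sites in the informative
subsequence, merges runs separated by at most ``max_gap_sites`` interrupting
``H`` sites (never across an ``R``), and emits a merged cluster as a segment
when it contains at least one run of ``min_run`` consecutive discordant
sites.  Single deterministic left-to-right pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discordance import sci3

_TRANSPARENT, _D, _H, _R = 0, 1, 2, 3


@dataclass(frozen=True)
class ScanParams:
    """Scan parameters.

    min_run is the number of consecutive discordant SNPs required to seed a
    segment (inclusive by default; set strict_min_run for a strictly-greater
    rule).  max_gap_sites is the number of interrupting concordant-het sites
    tolerated between merged runs.  extend_to_end reports a terminal segment
    as running to the scaffold end (telomere) instead of the last SNP.
    """

    min_run: int = 5
    max_gap_sites: int = 5
    strict_min_run: bool = False
    extend_to_end: bool = False

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.max_gap_sites < 0:
            raise ValueError("max_gap_sites must be >= 0")

    @property
    def effective_min_run(self) -> int:
        return self.min_run + 1 if self.strict_min_run else self.min_run


@dataclass(frozen=True)
class LohSegment:
    """A called LOH interval (1-based inclusive coordinates).

    n_sites counts every SNP inside [start, end]; consistency is the
    fraction of those not contradicting LOH, i.e. all but the interrupting
    concordant-het sites.
    """

    scaffold: str
    start: int
    end: int
    n_discordant: int
    n_interrupting_het: int
    n_concordant_hom: int
    n_sites: int
    segment_type: str = "loh"

    @property
    def consistency(self) -> float:
        return (self.n_sites - self.n_interrupting_het) / self.n_sites

    @property
    def consistency_pct(self) -> float:
        return round(100.0 * self.consistency, 2)


@dataclass(frozen=True)
class TransitionBracket:
    """Bracket around the het-to-hom transition.

    The true breakpoint lies between the last concordant-het site upstream of
    the segment (None when the segment starts at the first SNP of the
    scaffold) and the first discordant site.  An interval is reported, never
    a single guessed base.
    """

    scaffold: str
    last_het_pos: int | None
    first_discordant_pos: int

    @property
    def midpoint(self) -> float | None:
        if self.last_het_pos is None:
            return None
        return (self.last_het_pos + self.first_discordant_pos) / 2

    def contains(self, pos: int) -> bool:
        lo = self.last_het_pos if self.last_het_pos is not None else 0
        return lo <= pos <= self.first_discordant_pos

    def __str__(self) -> str:
        lo = "scaffold start" if self.last_het_pos is None else f"{self.last_het_pos:,}"
        return f"{self.scaffold}:({lo}; {self.first_discordant_pos:,})"


def classify_sites(code_wild: np.ndarray, code_sport: np.ndarray) -> np.ndarray:
    """Classify sites into transparent/D/H/R (see module docstring)."""
    cw = np.asarray(code_wild)
    cs = np.asarray(code_sport)
    cls = np.full(cw.shape, _TRANSPARENT, dtype=np.int8)
    wild_het = cw == 1
    sport_hom = (cs == 0) | (cs == 2)
    cls[wild_het & sport_hom] = _D
    cls[wild_het & (cs == 1)] = _H
    cls[~wild_het & (cs == 1)] = _R
    return cls


def _runs_of_d(sub: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of D in the informative subsequence, as [i, j) index
    pairs into that subsequence."""
    runs = []
    i = 0
    n = len(sub)
    while i < n:
        if sub[i] == _D:
            j = i
            while j < n and sub[j] == _D:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def find_loh_segments(
    sites: pd.DataFrame,
    params: ScanParams | None = None,
    scaffold_length: int | None = None,
) -> list[LohSegment]:
    """Call LOH segments on the coded sites of one scaffold.

    ``sites`` needs columns scaffold, pos, code_wild, code_sport, sorted by
    pos with no missing codes.  Segments are returned disjoint and sorted.
    """
    params = params or ScanParams()
    if len(sites) == 0:
        return []
    pos = sites["pos"].to_numpy()
    if np.any(np.diff(pos) < 0):
        bad = int(pos[np.argmax(np.diff(pos) < 0) + 1])
        raise ValueError(f"sites not sorted by position (first offender at {bad})")
    names = sites["scaffold"].unique()
    if len(names) != 1:
        raise ValueError("sites must come from exactly one scaffold")
    scaffold = str(names[0])

    cls = classify_sites(sites["code_wild"].to_numpy(), sites["code_sport"].to_numpy())
    informative = np.flatnonzero(cls != _TRANSPARENT)
    sub = cls[informative]
    runs = _runs_of_d(sub)
    if not runs:
        return []

    # merge runs transitively when separated by <= max_gap_sites H and no R
    clusters: list[list[tuple[int, int]]] = [[runs[0]]]
    for prev, cur in zip(runs, runs[1:]):
        between = sub[prev[1] : cur[0]]
        n_h = int((between == _H).sum())
        n_r = int((between == _R).sum())
        if n_h <= params.max_gap_sites and n_r == 0:
            clusters[-1].append(cur)
        else:
            clusters.append([cur])

    min_run = params.effective_min_run
    segments = []
    last_cluster = len(clusters) - 1
    for ci, cluster in enumerate(clusters):
        if max(j - i for i, j in cluster) < min_run:
            continue
        first = informative[cluster[0][0]]
        last = informative[cluster[-1][1] - 1]
        span = cls[first : last + 1]
        start = int(pos[first])
        end = int(pos[last])
        if params.extend_to_end and ci == last_cluster:
            if scaffold_length is None:
                raise ValueError("extend_to_end requires scaffold_length")
            end = int(scaffold_length)
        segments.append(
            LohSegment(
                scaffold=scaffold,
                start=start,
                end=end,
                n_discordant=int((span == _D).sum()),
                n_interrupting_het=int((span == _H).sum()),
                n_concordant_hom=int((span == _TRANSPARENT).sum()),
                n_sites=len(span),
            )
        )
    return segments


def locate_transition(sites: pd.DataFrame, segment: LohSegment) -> TransitionBracket:
    """Bracket the het-to-hom breakpoint of a called segment.

    The lower bound is the last site upstream of the segment that is
    heterozygous in both samples (retained heterozygosity); the upper bound
    is the segment's first discordant site.
    """
    pos = sites["pos"].to_numpy()
    cw = sites["code_wild"].to_numpy()
    cs = sites["code_sport"].to_numpy()
    upstream = (pos < segment.start) & (cw == 1) & (cs == 1)
    last_het = int(pos[upstream][-1]) if upstream.any() else None
    return TransitionBracket(segment.scaffold, last_het, segment.start)


def false_negative_rate(n_interrupting_het: int, span_bp: float) -> tuple[float, str]:
    """Het false-negative rate of a segment: interruptions per bp of span.

    Returns the exact rate and its 3-significant-figure string.
    """
    if span_bp <= 0:
        raise ValueError("span must be positive")
    rate = n_interrupting_het / span_bp
    return rate, sci3(rate)


def segments_table(segments: list[LohSegment]) -> pd.DataFrame:
    """Segment list as a report table."""
    return pd.DataFrame(
        [
            {
                "scaffold": s.scaffold,
                "start": s.start,
                "end": s.end,
                "n_sites": s.n_sites,
                "n_discordant": s.n_discordant,
                "n_interrupting_het": s.n_interrupting_het,
                "n_concordant_hom": s.n_concordant_hom,
                "consistency_pct": s.consistency_pct,
            }
            for s in segments
        ]
    )
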