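"""MORE cassette mining, matching, set building and enrichment.

A MORE (multiple organized regulatory element) cassette is an ordered,
strand-oriented tuple of 3-6 TFBS elements with a bounded distance range
between each adjacent pair, shared by a quorum of promoters. Distances are
measured start-to-start between adjacent matches on forward coordinates.

Mining is level-wise (a-priori style): supported ordered element pairs with
a common distance window seed the search, candidates grow one element at a
time, and every candidate's support and distance ranges are re-derived from
the actual occurrences, so each reported range is the tightest interval
covering the supporting matches.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

from .pwm import TfbsMatch

Element = tuple[str, str]  # (pwm_id, strand)


@dataclass(frozen=True)
class MiningParams:
    """FrameWorker-style mining parameters.

    ``dist_var`` bounds the width of each distance range (20 bp, with a
    30 bp fallback when nothing is found); ``min_dist`` is the minimal
    start-to-start distance between adjacent elements; cassettes carry
    between ``min_elements`` and ``max_elements`` elements and must be
    shared by at least ``quorum`` promoters.
    """

    min_elements: int = 3
    max_elements: int = 6
    quorum: int = 3
    dist_var: int = 20
    fallback_dist_var: int = 30
    min_dist: int = 10

    def __post_init__(self) -> None:
        if not (3 <= self.min_elements <= self.max_elements <= 6):
            raise ValueError("element count bounds must satisfy "
                             "3 <= min <= max <= 6")
        if self.quorum < 3:
            raise ValueError("quorum must be >= 3")
        if self.dist_var not in (20, 30):
            raise ValueError("dist_var must be 20 or 30")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")


@dataclass(frozen=True)
class MoreCassette:
    """An ordered TFBS cassette with per-gap distance ranges and support."""

    elements: tuple[Element, ...]
    distance_ranges: tuple[tuple[int, int], ...]
    support: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.distance_ranges) != len(self.elements) - 1:
            raise ValueError("need one distance range per adjacent pair")

    @property
    def label(self) -> str:
        return "-".join(f"{p}({s})" for p, s in self.elements)

    def reversed(self) -> "MoreCassette":
        """The same cassette read on the opposite strand."""
        flipped = tuple((p, "-" if s == "+" else "+")
                        for p, s in reversed(self.elements))
        return MoreCassette(flipped, tuple(reversed(self.distance_ranges)),
                            self.support)


@dataclass
class MoreSet:
    """Cassettes identical in elements/order (or near-identical, see
    :func:`build_more_sets`), treated as one regulatory signature."""

    id: str
    cassettes: list[MoreCassette]
    phenotype_tag: tuple[str, str, str] | None = None  # (parameter, sex, dir)

    @property
    def support(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.cassettes:
            out |= c.support
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of a cassette/set in a promoter set vs genome."""

    target_count: int
    expected: float
    ratio: float
    associated: bool
    control_ratio: float | None = None


# ---------------------------------------------------------------------------
# occurrence bookkeeping


def _starts_by_element(matches: list[TfbsMatch]) -> dict[Element, list[int]]:
    out: dict[Element, list[int]] = {}
    for m in matches:
        out.setdefault((m.pwm_id, m.strand), []).append(m.start)
    for starts in out.values():
        starts.sort()
    return {k: sorted(set(v)) for k, v in out.items()}


def _chain_occurrences(starts_by_elem: dict[Element, list[int]],
                       elements: tuple[Element, ...],
                       ranges: tuple[tuple[int, int], ...],
                       ) -> list[tuple[tuple[int, int], ...]] | None:
    """Per-gap usable start pairs for one promoter, or None when no full
    chain of the cassette exists.

    Reachability is computed forward and backward over the per-element
    match lists, so a pair is reported only if it lies on at least one
    complete chain; the union over pairs gives the tightest per-gap ranges.
    """
    lists = []
    for e in elements:
        starts = starts_by_elem.get(e)
        if not starts:
            return None
        lists.append(starts)
    k = len(elements)
    fwd: list[set[int]] = [set(range(len(lists[0])))]
    for j in range(k - 1):
        lo, hi = ranges[j]
        nxt = {b for b in range(len(lists[j + 1]))
               if any(lo <= lists[j + 1][b] - lists[j][a] <= hi
                      for a in fwd[j])}
        if not nxt:
            return None
        fwd.append(nxt)
    bwd: list[set[int]] = [set()] * k
    bwd[k - 1] = fwd[k - 1]
    for j in range(k - 2, -1, -1):
        lo, hi = ranges[j]
        bwd[j] = {a for a in fwd[j]
                  if any(lo <= lists[j + 1][b] - lists[j][a] <= hi
                         for b in bwd[j + 1])}
        if not bwd[j]:
            return None
    gap_pairs: list[tuple[tuple[int, int], ...]] = []
    for j in range(k - 1):
        lo, hi = ranges[j]
        pairs = tuple((lists[j][a], lists[j + 1][b])
                      for a in bwd[j] for b in bwd[j + 1]
                      if lo <= lists[j + 1][b] - lists[j][a] <= hi)
        gap_pairs.append(pairs)
    return gap_pairs


def _support_and_tighten(scans_by_elem: dict[str, dict[Element, list[int]]],
                         elements: tuple[Element, ...],
                         ranges: tuple[tuple[int, int], ...],
                         ) -> tuple[frozenset[str],
                                    tuple[tuple[int, int], ...]]:
    """Promoters containing the cassette, and ranges tightened to the
    occurrences actually found (subsets of the input windows)."""
    k = len(elements)
    support: set[str] = set()
    lo = [None] * (k - 1)
    hi = [None] * (k - 1)
    for pid, by_elem in scans_by_elem.items():
        gaps = _chain_occurrences(by_elem, elements, ranges)
        if gaps is None:
            continue
        support.add(pid)
        for j, pairs in enumerate(gaps):
            for a, b in pairs:
                d = b - a
                lo[j] = d if lo[j] is None else min(lo[j], d)
                hi[j] = d if hi[j] is None else max(hi[j], d)
    if not support:
        return frozenset(), ranges
    return frozenset(support), tuple((int(l), int(h))
                                     for l, h in zip(lo, hi))


# ---------------------------------------------------------------------------
# mining


def _pair_windows(scans_by_elem: dict[str, dict[Element, list[int]]],
                  quorum: int, dist_var: int, min_dist: int,
                  ) -> dict[tuple[Element, Element],
                            list[tuple[int, int]]]:
    """Frequent ordered element pairs with candidate distance windows.

    For each ordered pair of elements, every occurrence distance d seeds a
    window [d, d + dist_var]; windows covering occurrences in >= quorum
    distinct promoters are kept and tightened to the covered distances.
    """
    occ: dict[tuple[Element, Element], list[tuple[str, int]]] = {}
    for pid, by_elem in scans_by_elem.items():
        elems = list(by_elem)
        for ea, eb in itertools.product(elems, repeat=2):
            for sa in by_elem[ea]:
                for sb in by_elem[eb]:
                    d = sb - sa
                    if d >= min_dist:
                        occ.setdefault((ea, eb), []).append((pid, d))
    out: dict[tuple[Element, Element], list[tuple[int, int]]] = {}
    for key, occs in occ.items():
        dists = sorted({d for _, d in occs})
        windows: set[tuple[int, int]] = set()
        for d0 in dists:
            in_win = [(p, d) for p, d in occs if d0 <= d <= d0 + dist_var]
            if len({p for p, _ in in_win}) >= quorum:
                ds = [d for _, d in in_win]
                windows.add((min(ds), max(ds)))
        if windows:
            out[key] = sorted(windows)
    return out


def _mine_at(scans_by_elem: dict[str, dict[Element, list[int]]],
             params: MiningParams, quorum: int, dist_var: int,
             ) -> list[MoreCassette]:
    pair_wins = _pair_windows(scans_by_elem, quorum, dist_var,
                              params.min_dist)
    if not pair_wins:
        return []
    # level 2 candidates (not reported on their own: min_elements >= 3)
    level: dict[tuple[tuple[Element, ...], tuple[tuple[int, int], ...]],
                frozenset[str]] = {}
    for (ea, eb), wins in pair_wins.items():
        for win in wins:
            supp, tight = _support_and_tighten(scans_by_elem, (ea, eb),
                                               (win,))
            if len(supp) >= quorum:
                level[((ea, eb), tight)] = supp
    reported: dict[tuple[tuple[Element, ...],
                         tuple[tuple[int, int], ...]], frozenset[str]] = {}
    size = 2
    while level and size < params.max_elements:
        nxt: dict = {}
        for (elems, ranges), _supp in level.items():
            last = elems[-1]
            for (ea, eb), wins in pair_wins.items():
                if ea != last:
                    continue
                for win in wins:
                    cand_elems = elems + (eb,)
                    supp, tight = _support_and_tighten(
                        scans_by_elem, cand_elems, ranges + (win,))
                    if len(supp) >= quorum:
                        nxt[(cand_elems, tight)] = supp
        size += 1
        if size >= params.min_elements:
            reported.update(nxt)
        level = nxt
    cassettes = [MoreCassette(elems, ranges, supp)
                 for (elems, ranges), supp in reported.items()]
    return _suppress_subcassettes(cassettes)


def _suppress_subcassettes(cassettes: list[MoreCassette],
                           ) -> list[MoreCassette]:
    """Drop cassettes whose element list is a contiguous sub-list of a
    longer reported cassette with identical support (maximality)."""

    def is_sub(short: tuple, long: tuple) -> bool:
        n, m = len(short), len(long)
        return any(long[i:i + n] == short for i in range(m - n + 1))

    keep = []
    for c in cassettes:
        redundant = any(
            len(o.elements) > len(c.elements)
            and o.support == c.support
            and is_sub(c.elements, o.elements)
            for o in cassettes)
        if not redundant:
            keep.append(c)
    keep.sort(key=lambda c: (c.elements, c.distance_ranges,
                             sorted(c.support)))
    return keep


def mine_cassettes(promoter_scans: dict[str, list[TfbsMatch]],
                   params: MiningParams = MiningParams(),
                   adaptive: bool = True) -> list[MoreCassette]:
    """Mine MORE cassettes shared by promoters of one set.

    With ``adaptive=True`` (the default) the sequence quorum starts at the
    set size and is lowered step by step until cassettes appear, floored at
    3; if nothing is found at ``dist_var`` the search is repeated with the
    fallback distance variation (30 bp). An empty result means the promoter
    set is negative.
    """
    if len(promoter_scans) < 3:
        raise ValueError("need at least 3 promoters to mine cassettes")
    scans_by_elem = {pid: _starts_by_element(ms)
                     for pid, ms in promoter_scans.items()}
    dist_vars = ((params.dist_var, params.fallback_dist_var)
                 if adaptive else (params.dist_var,))
    quorums = (range(len(promoter_scans), max(params.quorum, 3) - 1, -1)
               if adaptive else (params.quorum,))
    for dv in dist_vars:
        for q in quorums:
            found = _mine_at(scans_by_elem, params, q, dv)
            if found:
                return found
    return []


# ---------------------------------------------------------------------------
# matching


def _rc_starts_by_element(by_elem: dict[Element, list[int]],
                          pwm_lengths: dict[str, int],
                          promoter_length: int) -> dict[Element, list[int]]:
    out: dict[Element, list[int]] = {}
    for (pwm_id, strand), starts in by_elem.items():
        L = pwm_lengths[pwm_id]
        flipped = "-" if strand == "+" else "+"
        out[(pwm_id, flipped)] = sorted(promoter_length - (s + L)
                                        for s in starts)
    return out


def match_cassette(cassette: MoreCassette | MoreSet,
                   promoter_scans: dict[str, list[TfbsMatch]],
                   promoter_lengths: dict[str, int] | None = None,
                   pwm_lengths: dict[str, int] | None = None,
                   ) -> dict[str, bool]:
    """Locate a cassette (or any member of a MORE set) in promoters.

    A promoter hits when it contains ordered, strand-consistent matches of
    every element with adjacent start-to-start distances inside the
    cassette's ranges. When promoter and PWM lengths are given the
    opposite-strand reading of each promoter is also tried, which picks up
    cassettes written on the reverse strand.
    """
    members = (cassette.cassettes if isinstance(cassette, MoreSet)
               else [cassette])
    hits: dict[str, bool] = {}
    for pid, matches in promoter_scans.items():
        by_elem = _starts_by_element(matches)
        views = [by_elem]
        if promoter_lengths is not None and pwm_lengths is not None:
            views.append(_rc_starts_by_element(by_elem, pwm_lengths,
                                               promoter_lengths[pid]))
        hit = False
        for cas in members:
            for view in views:
                if _chain_occurrences(view, cas.elements,
                                      cas.distance_ranges) is not None:
                    hit = True
                    break
            if hit:
                break
        hits[pid] = hit
    return hits


# ---------------------------------------------------------------------------
# MORE sets


def _mergeable(a: MoreCassette, b: MoreCassette) -> bool:
    if a.elements == b.elements:
        return True
    if len(a.elements) != len(b.elements) or len(a.elements) < 4:
        return False
    diffs = sum(x != y for x, y in zip(a.elements, b.elements))
    if diffs != 1:
        return False
    overlap = len(a.support & b.support) / min(len(a.support),
                                               len(b.support))
    return overlap > 0.8


def build_more_sets(cassettes: list[MoreCassette],
                    phenotype_tag: tuple[str, str, str] | None = None,
                    ) -> list[MoreSet]:
    """Group cassettes into MORE sets.

    Cassettes identical in all elements and order always share a set;
    cassettes of >= 4 elements differing in exactly one element at the same
    position also merge when their promoter-support overlap
    (|A∩B| / min(|A|,|B|)) exceeds 0.8. Grouping is transitive and
    independent of input order.
    """
    order = sorted(range(len(cassettes)),
                   key=lambda i: (cassettes[i].elements,
                                  cassettes[i].distance_ranges,
                                  sorted(cassettes[i].support)))
    parent = list(range(len(cassettes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ii, jj in itertools.combinations(order, 2):
        if _mergeable(cassettes[ii], cassettes[jj]):
            parent[find(ii)] = find(jj)
    groups: dict[int, list[MoreCassette]] = {}
    for i in order:
        groups.setdefault(find(i), []).append(cassettes[i])
    sets = []
    for members in groups.values():
        label = members[0].label
        if phenotype_tag is not None:
            label = f"{phenotype_tag[0]}-{phenotype_tag[1]}"\
                    f"{phenotype_tag[2][0]} {label}"
        sets.append(MoreSet(label, members, phenotype_tag))
    sets.sort(key=lambda s: s.id)
    return sets


# ---------------------------------------------------------------------------
# enrichment


def enrichment_from_counts(target_count: int, test_size: int,
                           genome_hits: int, genome_size: int,
                           control_count: int | None = None,
                           control_size: int | None = None,
                           ) -> EnrichmentResult:
    """Over-representation ratio of observed vs expected promoter hits.

    ``expected`` is the test-set size times the genome-wide hit rate; a
    ratio >= 2 flags an association. A genome-wide hit count of zero leaves
    the ratio undefined (reported as 0, not associated).
    """
    if genome_hits <= 0 or genome_size <= 0 or test_size <= 0:
        return EnrichmentResult(target_count, 0.0, 0.0, False)
    expected = test_size * genome_hits / genome_size
    ratio = target_count / expected
    control_ratio = None
    if control_count is not None and control_size:
        control_exp = control_size * genome_hits / genome_size
        control_ratio = control_count / control_exp if control_exp else 0.0
    return EnrichmentResult(target_count, expected, ratio, ratio >= 2.0,
                            control_ratio)


def enrichment(more_set: MoreSet | MoreCassette,
               test_scans: dict[str, list[TfbsMatch]],
               all_scans: dict[str, list[TfbsMatch]],
               control_scans: dict[str, list[TfbsMatch]] | None = None,
               promoter_lengths: dict[str, int] | None = None,
               pwm_lengths: dict[str, int] | None = None,
               ) -> EnrichmentResult:
    """Score a MORE set against a promoter set and the genome-wide
    background; optionally also against the opposite-phenotype control."""
    kw = dict(promoter_lengths=promoter_lengths, pwm_lengths=pwm_lengths)
    genome = match_cassette(more_set, all_scans, **kw)
    test = match_cassette(more_set, test_scans, **kw)
    control_count = control_size = None
    if control_scans is not None:
        control = match_cassette(more_set, control_scans, **kw)
        control_count = sum(control.values())
        control_size = len(control)
    return enrichment_from_counts(sum(test.values()), len(test),
                                  sum(genome.values()), len(genome),
                                  control_count, control_size)
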