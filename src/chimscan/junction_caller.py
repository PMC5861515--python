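"""Single-read break detection and chimeric-junction inference.

A read that crosses a chimeric junction maps to the genome in two collinear
pieces: a prefix anchored at one locus and a suffix anchored at another, with
a run of unmapped k-mers in between.  A read carrying a substitution
sequencing error shows the same unmapped gap, but (i) the two flanks are
contiguous on the genome and (ii) the k-mers covering the error are private
to that read, so their collection-wide support collapses to ~1 while the
flanks stay at the local coverage.  :func:`call_breaks` uses both signals to
separate errors from junctions; :func:`infer_junction` then resolves the
exact breakpoint, assigning micro-homologous bases to the 5' side (maximal
rightward extension of the left anchor) so all reads spanning one event
aggregate to a single (Pos1, Pos2) key.

Coordinates are 1-based inclusive throughout.  Pos1 is the genomic position
of the last transcribed base of the 5' fragment, Pos2 the first transcribed
base of the 3' fragment.

Limitations (by construction): a break within k bases of a read end has no
anchor on one side and is not callable; a read containing two breaks (two
junctions, or a junction plus an error inside an anchor) is not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chimera_core import GenomicSide
from .genomeindex import (KmerIndex, Location, LocationProfile,
                          SupportProfile, count_read_kmers, locate_profile,
                          support_profile)
from ._seq import complement

VERDICTS = ("error", "collinear_junction", "noncollinear_junction",
            "strand_switch", "interchromosomal")


@dataclass
class CallerConfig:
    """Tunables of the break caller.

    ``error_support``: a gap whose k-mer support dips to this value or below
    (default 1: the read itself) while both flanks exceed it is treated as a
    sequencing error when the flanks are genomically contiguous.
    ``anchor_min``: minimum genomic anchor length on each side of a junction
    (defaults to k). ``fragment_max``: maximum distance between a mate and
    its side of the junction for spanning-pair support.
    """

    error_support: int = 1
    anchor_min: int | None = None
    fragment_max: int = 1000
    protocol: str = "fr-firststrand"

    def min_anchor(self, k: int) -> int:
        return self.anchor_min if self.anchor_min is not None else k


@dataclass
class Anchor:
    """A maximal collinear chain of k-mer locations within a read."""

    chrom: str
    strand: int
    k: int
    first_offset: int      # first k-mer offset of the chain (0-based in read)
    last_offset: int       # last k-mer offset of the chain
    start_loc: int         # genomic start (1-based) of the k-mer at first_offset
    last_loc: int          # genomic start of the k-mer at last_offset

    def read_base_pos(self, read_index: int) -> int:
        """Genomic position of the read base at 0-based ``read_index``.

        Valid for bases covered by (an extension of) this alignment.
        """
        if self.strand == 1:
            return self.start_loc + (read_index - self.first_offset)
        # minus strand: the k-mer at offset o matches the reverse complement
        # of genome[start .. start+k-1], so read base r maps to
        # start + k - 1 - (r - o); successive k-mer starts decrease by 1,
        # which collapses to one affine map anchored at first_offset.
        return self.start_loc + self.k - 1 - (read_index - self.first_offset)


@dataclass
class BreakCall:
    """A detected break inside one read."""

    read_id: str
    read: str
    k: int
    verdict: str
    left: Anchor
    right: Anchor
    gap_offsets: tuple[int, int]  # inclusive k-mer offset range with no chained location

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass(frozen=True)
class JunctionCandidate:
    """A called junction with its supporting read(s) and genomic fragments."""

    left: GenomicSide
    right: GenomicSide
    read_ids: tuple[str, ...]
    left_fragment: tuple[str, int, int]
    right_fragment: tuple[str, int, int]

    @property
    def key(self):
        return (self.left, self.right)


def _successor(loc: Location) -> Location:
    chrom, pos, strand = loc
    return (chrom, pos + strand, strand)


def _predecessor(loc: Location) -> Location:
    chrom, pos, strand = loc
    return (chrom, pos - strand, strand)


def _prefix_chain(locs: list[list[Location]], start: int) -> tuple[Location, int]:
    """Longest collinear chain starting at offset ``start``; returns the
    chosen starting location and the last offset of the chain."""
    best_loc, best_end = None, start - 1
    for loc in locs[start]:
        cur = loc
        end = start
        while end + 1 < len(locs) and _successor(cur) in locs[end + 1]:
            cur = _successor(cur)
            end += 1
        if end > best_end or best_loc is None:
            best_loc, best_end = loc, end
    return best_loc, best_end


def _suffix_chain(locs: list[list[Location]], end: int) -> tuple[Location, int]:
    """Longest collinear chain ending at offset ``end``; returns the location
    at the chain start and the first offset of the chain."""
    best_loc, best_start = None, end + 1
    for loc in locs[end]:
        cur = loc
        start = end
        while start - 1 >= 0 and _predecessor(cur) in locs[start - 1]:
            cur = _predecessor(cur)
            start -= 1
        if start < best_start or best_loc is None:
            best_loc, best_start = cur, start
    return best_loc, best_start


def call_breaks(loc: LocationProfile, sup: SupportProfile,
                cfg: CallerConfig | None = None) -> list[BreakCall]:
    """Detect at most one break in a read from its two profiles.

    Returns an empty list for fully collinear reads, reads with no mapped
    k-mer, and reads whose break lies within k of a read end (no anchor on
    one side).  A verdict of ``"error"`` marks a pure-substitution
    signature: contiguous flanks plus a support dip in the gap; no junction
    should be emitted from such calls.
    """
    cfg = cfg or CallerConfig()
    locs = loc.locations
    mapped = [i for i, l in enumerate(locs) if l]
    if not mapped:
        return []
    first, last = mapped[0], mapped[-1]

    left_loc, left_end = _prefix_chain(locs, first)
    if left_end == len(locs) - 1:
        return []          # collinear to the read end: no break
    if last < len(locs) - 1:
        return []          # read end unmapped: break unanchorable
    right_loc, right_start = _suffix_chain(locs, last)
    if right_start <= left_end:
        # chains overlap in read offsets: a micro-homology wider than k-1
        # (a fully collinear read was already handled above, since its left
        # chain reaches the read end). If both chains are the same alignment,
        # there is no break.
        c1, p1, s1 = left_loc
        if (c1, p1 + s1 * (right_start - first), s1) == right_loc:
            return []

    left_anchor = Anchor(
        chrom=left_loc[0], strand=left_loc[2], k=loc.k,
        first_offset=first, last_offset=left_end,
        start_loc=left_loc[1],
        last_loc=left_loc[1] + left_loc[2] * (left_end - first),
    )
    right_anchor = Anchor(
        chrom=right_loc[0], strand=right_loc[2], k=loc.k,
        first_offset=right_start, last_offset=last,
        start_loc=right_loc[1],
        last_loc=right_loc[1] + right_loc[2] * (last - right_start),
    )
    gap = (left_end + 1, right_start - 1)

    # substitution signature: contiguous flanks + private-gap support dip
    c1, p1, s1 = left_loc
    extrap_to_right = (c1, p1 + s1 * (right_start - first), s1)
    contiguous = extrap_to_right == (right_anchor.chrom, right_anchor.start_loc,
                                     right_anchor.strand)
    if contiguous and gap[0] <= gap[1]:
        gap_sup = min(sup.counts[i] for i in range(gap[0], gap[1] + 1))
        flank_sup = min(sup.counts[left_end], sup.counts[right_start])
        if gap_sup <= cfg.error_support < flank_sup:
            verdict = "error"
            return [BreakCall(loc.read_id, loc.read, loc.k, verdict,
                              left_anchor, right_anchor, gap)]

    k = loc.k
    # genomic positions of the last read base of the left anchor and the
    # first read base of the right anchor
    left_last_base = left_anchor.read_base_pos(left_end + k - 1)
    right_first_base = right_anchor.read_base_pos(right_start)
    if left_anchor.chrom != right_anchor.chrom:
        verdict = "interchromosomal"
    elif left_anchor.strand != right_anchor.strand:
        verdict = "strand_switch"
    elif (left_anchor.strand == 1 and right_first_base > left_last_base) or \
         (left_anchor.strand == -1 and right_first_base < left_last_base):
        verdict = "collinear_junction"
    else:
        verdict = "noncollinear_junction"
    return [BreakCall(loc.read_id, loc.read, loc.k, verdict,
                      left_anchor, right_anchor, gap)]


def _sense_base(genome, chrom: str, pos: int, strand: int) -> str | None:
    seq = genome.chromosomes[chrom]
    if pos < 1 or pos > len(seq):
        return None
    base = seq[pos - 1]
    return base if strand == 1 else complement(base)


def infer_junction(call: BreakCall, genome,
                   cfg: CallerConfig | None = None) -> JunctionCandidate | None:
    """Resolve a break call into exact junction coordinates.

    The left anchor is extended rightward base-by-base as long as the read
    keeps matching the left locus: micro-homologous bases at the junction are
    thereby assigned to the 5' side, which canonicalizes the breakpoint so
    that every spanning read of one event yields the same (Pos1, Pos2).
    Returns ``None`` when either anchor (after extension) is shorter than
    ``cfg.anchor_min`` genomic bases.
    """
    if call.verdict == "error":
        raise ValueError("cannot infer a junction from an error call")
    cfg = cfg or CallerConfig()
    read = call.read
    k = call.k
    la, ra = call.left, call.right

    # maximal rightward extension of the left anchor
    r = la.last_offset + k - 1                      # last read base index covered
    g = la.read_base_pos(r)
    while r + 1 < len(read):
        nxt = _sense_base(genome, la.chrom, g + la.strand, la.strand)
        if nxt is None or nxt != read[r + 1]:
            break
        r += 1
        g += la.strand
    junction_read_idx = r                           # last 5' base in the read
    pos1 = g

    # maximal leftward extension of the right anchor
    rb = ra.first_offset
    g2 = ra.read_base_pos(rb)
    while rb - 1 >= 0:
        prv = _sense_base(genome, ra.chrom, g2 - ra.strand, ra.strand)
        if prv is None or prv != read[rb - 1]:
            break
        rb -= 1
        g2 -= ra.strand
    if rb > junction_read_idx + 1:
        return None                                 # alignments do not meet
    pos2 = g2 + ra.strand * (junction_read_idx + 1 - rb)

    left_len = junction_read_idx - la.first_offset + 1
    right_len = len(read) - (junction_read_idx + 1)
    if left_len < cfg.min_anchor(k) or right_len < cfg.min_anchor(k):
        return None

    left_span = sorted((la.read_base_pos(la.first_offset), pos1))
    right_span = sorted((pos2, ra.read_base_pos(len(read) - 1)))
    return JunctionCandidate(
        left=GenomicSide(la.chrom, pos1, la.strand),
        right=GenomicSide(ra.chrom, pos2, ra.strand),
        read_ids=(call.read_id,),
        left_fragment=(la.chrom, left_span[0], left_span[1]),
        right_fragment=(ra.chrom, right_span[0], right_span[1]),
    )


def flip_candidate(cand: JunctionCandidate) -> JunctionCandidate:
    """Re-express a junction observed on the antisense strand in sense
    orientation: sides swap and strands invert (the fragment intervals are
    strandless and simply swap)."""
    return JunctionCandidate(
        left=GenomicSide(cand.right.chrom, cand.right.pos, -cand.right.strand),
        right=GenomicSide(cand.left.chrom, cand.left.pos, -cand.left.strand),
        read_ids=cand.read_ids,
        left_fragment=cand.right_fragment,
        right_fragment=cand.left_fragment,
    )


def canonicalize_candidate(cand: JunctionCandidate, genome) -> JunctionCandidate:
    """Left-shift micro-homology: while the next transcript-sense base past
    Pos1 on the 5' locus equals the base at Pos2 on the 3' locus, move the
    junction one base forward in transcription order on both sides.

    Candidates inferred from sense reads are already maximal (a no-op);
    candidates flipped from antisense reads were canonicalized in the
    opposite direction and shift back here, so both mates of a stranded
    library aggregate to one (Pos1, Pos2) key.
    """
    L, R = cand.left, cand.right
    right_len = cand.right_fragment[2] - cand.right_fragment[1] + 1
    h = 0
    while h < right_len - 1:
        nxt = _sense_base(genome, L.chrom, L.pos + L.strand * (h + 1), L.strand)
        cur = _sense_base(genome, R.chrom, R.pos + R.strand * h, R.strand)
        if nxt is None or cur is None or nxt != cur:
            break
        h += 1
    if h == 0:
        return cand
    lf, rf = cand.left_fragment, cand.right_fragment
    lf = (lf[0], lf[1], lf[2] + h) if L.strand == 1 else (lf[0], lf[1] - h, lf[2])
    rf = (rf[0], rf[1] + h, rf[2]) if R.strand == 1 else (rf[0], rf[1], rf[2] - h)
    return JunctionCandidate(
        left=GenomicSide(L.chrom, L.pos + L.strand * h, L.strand),
        right=GenomicSide(R.chrom, R.pos + R.strand * h, R.strand),
        read_ids=cand.read_ids, left_fragment=lf, right_fragment=rf,
    )


def call_junctions(reads, index: KmerIndex, genome, kmer_counts=None,
                   cfg: CallerConfig | None = None, antisense_ids=None):
    """Profile every read, call breaks, and return merged junction candidates.

    ``reads`` is an iterable of ``(read_id, sequence)``.  ``antisense_ids``
    names reads sequenced antisense to the transcript (mate 1 under the dUTP
    protocol): their candidates are flipped into sense orientation before
    merging.  All candidates are micro-homology canonicalized, so one event
    yields one (left, right) key regardless of which mate observed it.
    Returns ``(candidates, stats)``.
    """
    cfg = cfg or CallerConfig()
    reads = list(reads)
    antisense_ids = antisense_ids or set()
    if kmer_counts is None:
        kmer_counts = count_read_kmers((seq for _, seq in reads), index.k)
    merged: dict[tuple, dict] = {}
    order = []
    stats = {"reads": 0, "unmapped_or_collinear": 0, "error": 0,
             "junction_calls": 0, "rejected_anchor": 0}
    for read_id, seq in reads:
        stats["reads"] += 1
        if len(seq) < index.k:
            stats["unmapped_or_collinear"] += 1
            continue
        lp = locate_profile(seq, index, read_id=read_id)
        sp = support_profile(seq, kmer_counts, index.k, read_id=read_id)
        calls = call_breaks(lp, sp, cfg)
        if not calls:
            stats["unmapped_or_collinear"] += 1
            continue
        for call in calls:
            if call.verdict == "error":
                stats["error"] += 1
                continue
            cand = infer_junction(call, genome, cfg)
            if cand is None:
                stats["rejected_anchor"] += 1
                continue
            if read_id in antisense_ids:
                cand = flip_candidate(cand)
            cand = canonicalize_candidate(cand, genome)
            stats["junction_calls"] += 1
            key = cand.key
            if key not in merged:
                order.append(key)
                merged[key] = {"reads": set(), "lf": cand.left_fragment,
                               "rf": cand.right_fragment}
            slot = merged[key]
            slot["reads"].update(cand.read_ids)
            slot["lf"] = (slot["lf"][0], min(slot["lf"][1], cand.left_fragment[1]),
                          max(slot["lf"][2], cand.left_fragment[2]))
            slot["rf"] = (slot["rf"][0], min(slot["rf"][1], cand.right_fragment[1]),
                          max(slot["rf"][2], cand.right_fragment[2]))

    candidates = [
        JunctionCandidate(left=key[0], right=key[1],
                          read_ids=tuple(sorted(merged[key]["reads"])),
                          left_fragment=merged[key]["lf"],
                          right_fragment=merged[key]["rf"])
        for key in order
    ]
    return candidates, stats


def _full_alignment(seq: str, index: KmerIndex):
    """Collinear full-read alignment, or None if the read does not map as a
    single contiguous chain.  Returns (chrom, start, end, strand) where
    strand is the genome strand matched by the read sequence."""
    if len(seq) < index.k:
        return None
    lp = locate_profile(seq, index)
    locs = lp.locations
    if not locs[0]:
        return None
    best = None
    for loc in locs[0]:
        cur = loc
        ok = True
        for i in range(1, len(locs)):
            cur = _successor(cur)
            if cur not in locs[i]:
                ok = False
                break
        if ok:
            best = loc
            break
    if best is None:
        return None
    chrom, p, s = best
    k = index.k
    n = len(seq)
    if s == 1:
        return (chrom, p, p + n - 1, 1)
    # read base 0 maps to p + k - 1; last base maps to p - (n - 1) + k - 1
    return (chrom, p - (n - k), p + k - 1, -1)


def find_spanning_pairs(candidates, pairs, index: KmerIndex,
                        cfg: CallerConfig | None = None) -> dict:
    """Count read pairs whose mates flank a junction without covering it.

    ``pairs`` is an iterable of ``(pair_id, mate1_seq, mate2_seq)``.  Under
    the dUTP stranded protocol (``fr-firststrand``) mate 2 carries the
    transcript sense and sits at the fragment 5' end, mate 1 the antisense at
    the 3' end; a pair supports a candidate when the sense mate maps
    collinearly on the 5' partner locus within ``fragment_max`` bases
    upstream of Pos1, and the antisense mate on the 3' partner locus within
    ``fragment_max`` downstream of Pos2.  Mates that themselves cross the
    junction do not align collinearly and are therefore never counted here
    (they are spanning-junction reads instead).

    Returns ``{(left, right): set of pair ids}``.
    """
    cfg = cfg or CallerConfig()
    support: dict[tuple, set] = {c.key: set() for c in candidates}
    fm = cfg.fragment_max
    swap = cfg.protocol == "fr-secondstrand"

    for pair_id, m1, m2 in pairs:
        sense_mate, anti_mate = (m1, m2) if swap else (m2, m1)
        a_sense = _full_alignment(sense_mate, index)
        a_anti = _full_alignment(anti_mate, index)
        if a_sense is None or a_anti is None:
            continue
        for cand in candidates:
            L, R = cand.left, cand.right
            cs, ss, es, strs = a_sense
            ca, sa, ea, stra = a_anti
            # sense mate upstream of Pos1 on the 5' locus, sense orientation
            if cs != L.chrom or strs != L.strand:
                continue
            if L.strand == 1:
                up_ok = es <= L.pos and (L.pos - ss + 1) <= fm
            else:
                up_ok = ss >= L.pos and (es - L.pos + 1) <= fm
            if not up_ok:
                continue
            # antisense mate downstream of Pos2 on the 3' locus
            if ca != R.chrom or stra != -R.strand:
                continue
            if R.strand == 1:
                down_ok = sa >= R.pos and (ea - R.pos + 1) <= fm
            else:
                down_ok = ea <= R.pos and (R.pos - sa + 1) <= fm
            if not down_ok:
                continue
            support[cand.key].add(pair_id)
    return support
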