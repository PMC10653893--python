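"""Six-frame ORF calling with optional amber (TAG) read-through.

Pyrrolysine-containing genes are systematically truncated by standard gene
callers because the Pyl codon is the amber stop.  This module recovers them
by allowing up to ``max_readthroughs`` in-frame TAG codons to be crossed
(each emitting 'O'); TAA and TGA always terminate.

All coordinates are 0-based, half-open, forward-strand; the span includes
the terminating stop codon.  Minus-strand ORFs carry strand '-' and their
protein comes from the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .seq_io import (
    AMBER,
    CODON_TABLE,
    HARD_STOPS,
    SeqIOError,
    SeqRecord,
    reverse_complement,
)

DEFAULT_STARTS = frozenset({"ATG", "GTG", "TTG"})


@dataclass
class OrfCall:
    scaffold_id: str
    start: int
    end: int  # half-open, includes the stop codon
    strand: Literal["+", "-"]
    readthrough_offsets: list[int]  # codon indices translated as Pyl
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span not a multiple of 3")
        if self.protein.count("O") != len(self.readthrough_offsets):
            raise ValueError("readthrough offsets inconsistent with protein")
        if any(b <= a for a, b in zip(self.readthrough_offsets, self.readthrough_offsets[1:])):
            raise ValueError("readthrough offsets must be strictly increasing")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain '*'")

    @property
    def n_readthrough(self) -> int:
        return len(self.readthrough_offsets)


def _codons(seq: str, frame: int) -> list[str]:
    return [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]


def _orfs_one_frame(
    seq: str,
    frame: int,
    min_aa: int,
    starts: frozenset[str],
    mode: str,
    max_readthroughs: int,
) -> list[tuple[int, int, list[int], str]]:
    """ORFs on the given strand/frame as (codon_start_idx, codon_end_idx_inclusive_stop, offsets, protein).

    Returns only the longest ORF per terminator (the earliest start in the
    segment); in read-through modes a TAG crossed within budget does not
    terminate, so the effective terminator is the first hard stop or the
    (max_readthroughs+1)-th TAG.
    """
    codons = _codons(seq, frame)
    n = len(codons)
    out: list[tuple[int, int, list[int], str]] = []

    # segment boundaries at every terminator codon in 'standard' reading
    def is_stop(c: str) -> bool:
        return c in HARD_STOPS or c == AMBER

    if mode in ("standard", "both"):
        seg_start = 0
        i = 0
        while i < n:
            if is_stop(codons[i]):
                # earliest start in [seg_start, i)
                for j in range(seg_start, i):
                    if codons[j] in starts:
                        if i - j >= min_aa:
                            prot = "".join(
                                "X" if "N" in c else CODON_TABLE[c] for c in codons[j:i]
                            )
                            out.append((j, i, [], prot))
                        break
                seg_start = i + 1
            i += 1

    if mode in ("readthrough", "both"):
        # terminator = first hard stop, crossing up to max_readthroughs TAGs;
        # if the TAG budget is exhausted the next TAG terminates.
        i = 0
        seg_start = 0
        hard_positions = [k for k, c in enumerate(codons) if c in HARD_STOPS]
        amber_positions = [k for k, c in enumerate(codons) if c == AMBER]
        # walk segments between hard stops; within each, enumerate terminators
        # defined by the amber budget.
        boundaries = [-1] + hard_positions
        for b_idx in range(len(boundaries)):
            lo = boundaries[b_idx] + 1
            # trailing segment has no hard stop: ORFs there may still end at
            # an amber once the read-through budget is spent
            trailing = b_idx + 1 >= len(boundaries)
            hi = n if trailing else boundaries[b_idx + 1]
            ambers_in = [a for a in amber_positions if lo <= a < hi]
            # terminators for ORFs starting in this hard-stop segment chain:
            # an ORF starting at s in [lo, hi) may cross ambers after s.
            # The longest ORF per terminator rule: for terminator t (a hard
            # stop or an amber beyond budget), take the earliest valid start.
            # Enumerate candidate terminators: hi always; plus the amber that
            # exceeds the budget for early-enough starts.
            # For each start s (earliest first), its terminator is:
            #   ambers_after = ambers_in with a >= s
            #   if len(ambers_after) <= max_readthroughs: t = hi
            #   else: t = ambers_after[max_readthroughs]
            seen_terms: set[int] = set()
            for s in range(lo, hi):
                if codons[s] not in starts:
                    continue
                ambers_after = [a for a in ambers_in if a >= s]
                if len(ambers_after) <= max_readthroughs:
                    if trailing:
                        continue  # runs off the scaffold with no terminator
                    t = hi
                else:
                    t = ambers_after[max_readthroughs]
                if t in seen_terms:
                    continue
                seen_terms.add(t)
                if t - s >= min_aa:
                    prot_chars = []
                    offsets = []
                    for k in range(s, t):
                        c = codons[k]
                        if "N" in c:
                            prot_chars.append("X")
                        elif c == AMBER:
                            prot_chars.append("O")
                            offsets.append(k - s)
                        else:
                            prot_chars.append(CODON_TABLE[c])
                    if mode == "both" and not offsets:
                        continue  # identical to the standard call
                    out.append((s, t, offsets, "".join(prot_chars)))
    return out


def call_orfs(
    scaffold: SeqRecord,
    min_aa: int = 100,
    starts: Sequence[str] = tuple(sorted(DEFAULT_STARTS)),
    mode: Literal["standard", "readthrough", "both"] = "standard",
    max_readthroughs: int = 1,
) -> list[OrfCall]:
    """Call ORFs on all six frames of a nucleotide scaffold.

    An ORF begins at a start codon (default ATG/GTG/TTG) and ends at the
    first terminator; only the longest ORF per (frame, terminator) is
    reported.  ``mode='readthrough'`` crosses up to ``max_readthroughs``
    in-frame TAGs (each emitted as 'O'); ``mode='both'`` returns standard
    TAG-terminated calls plus each read-through extension.
    """
    if scaffold.moltype != "nucleotide":
        raise SeqIOError(f"call_orfs requires a nucleotide scaffold, got {scaffold.moltype}")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if max_readthroughs < 0:
        raise ValueError("max_readthroughs must be >= 0")
    starts_set = frozenset(s.upper() for s in starts)
    fwd = scaffold.upper
    rev = reverse_complement(fwd)
    L = len(fwd)
    calls: list[OrfCall] = []
    for strand, seq in (("+", fwd), ("-", rev)):
        for frame in (0, 1, 2):
            for cs, ce, offsets, prot in _orfs_one_frame(
                seq, frame, min_aa, starts_set, mode, max_readthroughs
            ):
                s_nt = frame + 3 * cs
                e_nt = frame + 3 * (ce + 1)  # include stop codon
                if strand == "+":
                    start, end = s_nt, e_nt
                else:
                    start, end = L - e_nt, L - s_nt
                calls.append(
                    OrfCall(
                        scaffold_id=scaffold.id,
                        start=start,
                        end=end,
                        strand=strand,
                        readthrough_offsets=offsets,
                        protein=prot,
                    )
                )
    calls.sort(key=lambda c: (c.scaffold_id, c.start, c.strand, c.end, c.n_readthrough))
    return calls


def orf_nt_span(call: OrfCall, scaffold: SeqRecord) -> str:
    """Forward-strand-oriented coding sequence of an ORF (stop included)."""
    seg = scaffold.upper[call.start : call.end]
    return seg if call.strand == "+" else reverse_complement(seg)


def recall_truncated(
    scaffold: SeqRecord,
    region: tuple[int, int],
    strand: Literal["+", "-"],
    anchor: SeqRecord,
    min_anchor_fraction: float = 0.8,
    max_readthroughs: int = 1,
    min_aa: int = 1,
    starts: Sequence[str] = tuple(sorted(DEFAULT_STARTS)),
) -> Optional[OrfCall]:
    """Re-call a truncated candidate with amber read-through.

    ``region`` is the forward-strand span of the truncated (TAG-terminated)
    call.  Returns the read-through ORF covering that region if its protein
    reaches at least ``min_anchor_fraction`` of the anchor protein's length;
    ``None`` otherwise.  If no in-frame TAG exists the standard ORF for the
    region is returned unchanged (subject to the same length gate).
    """
    lo, hi = region
    if lo < 0 or hi > len(scaffold) or lo >= hi:
        raise ValueError(f"region {region} outside scaffold {scaffold.id!r} (len {len(scaffold)})")
    calls = call_orfs(
        scaffold,
        min_aa=min_aa,
        starts=starts,
        mode="both",
        max_readthroughs=max_readthroughs,
    )
    covering = [
        c
        for c in calls
        if c.strand == strand and c.start <= lo and c.end >= hi
    ]
    if not covering:
        # fall back to standard calls overlapping the region
        covering = [
            c for c in calls if c.strand == strand and max(c.start, lo) < min(c.end, hi)
        ]
    if not covering:
        return None
    best = max(covering, key=lambda c: (len(c.protein), c.n_readthrough))
    if len(best.protein) >= min_anchor_fraction * len(anchor):
        return best
    return None
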