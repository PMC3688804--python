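"""Ultraconserved-element discovery from pairwise genome alignments.

A conserved core is a maximal run of alignment columns that are gap-free,
unambiguous (A/C/G/T only, case-insensitive) and identical between the two
genomes, strictly longer than the configured minimum (default 80 bp).  Cores
are buffered to the probe-design length (default 180 bp) with flanking
sequence from the buffering genome, validated by realignment against every
genome in the comparison set (exactly one qualifying match per genome), and
thinned so retained loci are separated by more than the minimum spacing
(default 10 kbp) in every genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io import AlignmentBlock

_UNAMBIGUOUS = frozenset("ACGT")

# status flags for a locus as it moves through validation
VALIDATED = "validated"
DROPPED_DUPLICATE = "dropped_duplicate"
DROPPED_SPACING = "dropped_spacing"
DROPPED_FLANK = "dropped_flank"
DROPPED_NO_MATCH = "dropped_no_match"


@dataclass
class ConservedElement:
    id: str
    ref_name: str
    ref_start: int   # 0-based half-open on the reference genome
    ref_end: int
    buffered_seq: str = ""
    buffer_start: int = -1   # ref coordinate of buffered_seq[0]
    status: str = ""

    @property
    def core_len(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class Placement:
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    match_len: int


@dataclass
class UceLocus:
    id: str
    placements: dict[str, Placement] = field(default_factory=dict)
    status: str = VALIDATED
    element: ConservedElement | None = None


def scan_conserved(block: AlignmentBlock, min_len: int = 80
                   ) -> list[ConservedElement]:
    """Find maximal perfectly conserved runs strictly longer than ``min_len``.

    A column counts as conserved only when both rows carry the same
    unambiguous base (no gaps, no N/IUPAC ambiguity).  Runs are reported in
    reference coordinates; the result is symmetric in the two rows.
    """
    elements: list[ConservedElement] = []
    ref_pos = block.ref_start
    run_start = None   # ref coordinate where the current run began
    run_len = 0

    def close_run() -> None:
        nonlocal run_start, run_len
        if run_start is not None and run_len > min_len:
            idx = len(elements)
            elements.append(ConservedElement(
                id=f"{block.ref_name}_uce{idx}",
                ref_name=block.ref_name,
                ref_start=run_start,
                ref_end=run_start + run_len,
            ))
        run_start, run_len = None, 0

    for r, q in zip(block.ref_seq.upper(), block.query_seq.upper()):
        conserved = r == q and r in _UNAMBIGUOUS
        if conserved:
            if run_start is None:
                run_start = ref_pos
            run_len += 1
        else:
            close_run()
        if r != "-":
            ref_pos += 1
    close_run()
    return elements


def buffer_element(elem: ConservedElement, genome_seq: str,
                   buffer_len: int = 180) -> ConservedElement:
    """Extend a core to ``buffer_len`` with flanking genome sequence.

    Flanks are split as evenly as possible; an odd leftover base goes to the
    3' side.  Elements too close to a sequence end to buffer fully are
    flagged ``dropped_flank`` rather than padded.
    """
    core = elem.core_len
    if core >= buffer_len:
        seq = genome_seq[elem.ref_start:elem.ref_end]
        return replace(elem, buffered_seq=seq, buffer_start=elem.ref_start,
                       status="")
    pad = buffer_len - core
    left = pad // 2
    right = pad - left
    start = elem.ref_start - left
    end = elem.ref_end + right
    if start < 0 or end > len(genome_seq):
        return replace(elem, status=DROPPED_FLANK)
    return replace(elem, buffered_seq=genome_seq[start:end],
                   buffer_start=start, status="")


def validate_across_genomes(elements: list[ConservedElement],
                            genomes: dict[str, dict[str, str]],
                            matcher,
                            min_match_len: int = 120,
                            min_identity: float = 0.80) -> list[UceLocus]:
    """Realign buffered elements to every genome; keep single-copy hits.

    ``genomes`` maps genome name -> {chrom -> sequence}.  ``matcher`` is the
    seeded local aligner ``local_match(query, target)`` returning None or an
    object with identity/span/orientation/target coordinates.  A locus is
    validated only when every genome yields exactly one qualifying match
    (span >= ``min_match_len``, identity >= ``min_identity``); two or more
    qualifying matches in any genome mark it ``dropped_duplicate``.
    """
    loci: list[UceLocus] = []
    for elem in elements:
        if elem.status == DROPPED_FLANK or not elem.buffered_seq:
            loci.append(UceLocus(elem.id, status=DROPPED_FLANK, element=elem))
            continue
        locus = UceLocus(elem.id, element=elem)
        for genome_name, chroms in genomes.items():
            hits = []
            for chrom_name, chrom_seq in chroms.items():
                for hit in matcher.find_all(elem.buffered_seq, chrom_seq):
                    if (hit.span >= min_match_len
                            and hit.identity >= min_identity):
                        hits.append((chrom_name, hit))
            if len(hits) == 0:
                locus.status = DROPPED_NO_MATCH
                break
            if len(hits) > 1:
                locus.status = DROPPED_DUPLICATE
                break
            chrom_name, hit = hits[0]
            locus.placements[genome_name] = Placement(
                chrom=chrom_name, start=hit.target_start, end=hit.target_end,
                strand=hit.orientation, identity=hit.identity,
                match_len=hit.span)
        loci.append(locus)
    return loci


def spacing_filter(loci: list[UceLocus], min_spacing: int = 10_000
                   ) -> list[UceLocus]:
    """Thin validated loci so retained ones are > ``min_spacing`` apart.

    Deterministic greedy sweep per genome, ordered by start coordinate (ties
    broken by longer core, then lexicographic id): a locus is dropped when
    its edge-to-edge gap to the previously retained locus is <= the minimum
    in any genome.  Dropped loci get status ``dropped_spacing``; the function
    is idempotent.
    """
    validated = [loc for loc in loci if loc.status == VALIDATED]
    dropped: set[str] = set()
    genome_names = sorted({g for loc in validated for g in loc.placements})
    for genome in genome_names:
        placed = [loc for loc in validated
                  if genome in loc.placements and loc.id not in dropped]

        def sort_key(loc: UceLocus):
            p = loc.placements[genome]
            core = loc.element.core_len if loc.element else p.end - p.start
            return (p.chrom, p.start, -core, loc.id)

        placed.sort(key=sort_key)
        last_end: dict[str, int] = {}
        for loc in placed:
            p = loc.placements[genome]
            prev = last_end.get(p.chrom)
            if prev is not None and p.start - prev <= min_spacing:
                dropped.add(loc.id)
                continue
            last_end[p.chrom] = p.end
    for loc in validated:
        if loc.id in dropped:
            loc.status = DROPPED_SPACING
    return list(loci)
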