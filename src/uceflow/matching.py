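"""Contig-to-locus matching with duplicate removal.

A seeded gapped local aligner (k-mer seeding + Smith-Waterman-style
extension via Bio.Align.PairwiseAligner) stands in for LASTZ.  Matching a
taxon's assembled contigs against the probe set enforces one-to-one
orthology: contigs hitting several loci (non-reciprocal duplicates) and loci
hit by several contigs (reciprocal duplicates) are both removed.  Matches
populate a relational store of taxa x loci x match records.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Align import PairwiseAligner

from .config import PipelineConfig
from .io import FastaRecord, write_tsv

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LocalHit:
    score: float
    identity: float
    span: int            # alignment columns, gaps included
    orientation: str     # strand of the query relative to the target
    target_start: int    # 0-based half-open on the target forward strand
    target_end: int
    query_start: int
    query_end: int


class SeededLocalMatcher:
    """k-mer seeded local aligner; LASTZ replacement for probe-scale queries.

    Default scoring: match +1, mismatch -1, gap open -4, gap extend -1
    (the opening gap character scores -4, each further one -1).  Queries
    shorter than the seed length never match.
    """

    def __init__(self, k: int = 20, match: int = 1, mismatch: int = -1,
                 gap_open: int = -4, gap_extend: int = -1):
        self.k = k
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap_open
        aligner.extend_gap_score = gap_extend
        self.aligner = aligner
        self._index_cache: OrderedDict[str, dict] = OrderedDict()

    # -- seeding ------------------------------------------------------------

    def _target_index(self, target: str) -> dict[str, list[int]]:
        cached = self._index_cache.get(target)
        if cached is not None:
            return cached
        index: dict[str, list[int]] = {}
        upper = target.upper()
        for i in range(len(upper) - self.k + 1):
            index.setdefault(upper[i:i + self.k], []).append(i)
        self._index_cache[target] = index
        while len(self._index_cache) > 8:
            self._index_cache.popitem(last=False)
        return index

    def _seed_positions(self, query: str, target: str) -> list[int]:
        index = self._target_index(target)
        upper = query.upper()
        positions: set[int] = set()
        for i in range(len(upper) - self.k + 1):
            kmer = upper[i:i + self.k]
            if "N" in kmer:
                continue
            for pos in index.get(kmer, ()):
                positions.add(pos)
        return sorted(positions)

    # -- alignment ----------------------------------------------------------

    def _align_window(self, query: str, target: str, w0: int, w1: int,
                      orientation: str) -> LocalHit | None:
        alignments = self.aligner.align(target[w0:w1].upper(), query.upper())
        if len(alignments) == 0:
            return None
        aln = alignments[0]
        counts = aln.counts()
        span = counts.gaps + counts.identities + counts.mismatches
        if span == 0:
            return None
        t_blocks, q_blocks = aln.aligned
        return LocalHit(
            score=aln.score,
            identity=counts.identities / span,
            span=span,
            orientation=orientation,
            target_start=w0 + int(t_blocks[0][0]),
            target_end=w0 + int(t_blocks[-1][1]),
            query_start=int(q_blocks[0][0]),
            query_end=int(q_blocks[-1][1]),
        )

    def find_all(self, query: str, target: str) -> list[LocalHit]:
        """All distinct local hits of ``query`` on either strand of ``target``.

        Seed positions closer than one query length are clustered into a
        single candidate window; overlapping hits are merged keeping the
        best-scoring one, so a tandem duplication yields two hits but one
        site never yields more than one.
        """
        qlen = len(query)
        hits: list[LocalHit] = []
        for orientation in "+-":
            q = query if orientation == "+" else revcomp(query)
            positions = self._seed_positions(q, target)
            if not positions:
                continue
            clusters: list[list[int]] = [[positions[0]]]
            for pos in positions[1:]:
                if pos - clusters[-1][-1] > qlen:
                    clusters.append([pos])
                else:
                    clusters[-1].append(pos)
            for cluster in clusters:
                w0 = max(0, cluster[0] - qlen)
                w1 = min(len(target), cluster[-1] + self.k + qlen)
                hit = self._align_window(q, target, w0, w1, orientation)
                if hit is not None:
                    hits.append(hit)
        return _merge_overlapping(hits)

    def best(self, query: str, target: str) -> LocalHit | None:
        hits = self.find_all(query, target)
        if not hits:
            return None
        return max(hits, key=lambda h: (h.score, -h.target_start))


def _merge_overlapping(hits: list[LocalHit]) -> list[LocalHit]:
    hits = sorted(hits, key=lambda h: (h.target_start, -h.score))
    merged: list[LocalHit] = []
    for hit in hits:
        absorbed = False
        for i, kept in enumerate(merged):
            overlap = (min(hit.target_end, kept.target_end)
                       - max(hit.target_start, kept.target_start))
            shorter = min(hit.target_end - hit.target_start,
                          kept.target_end - kept.target_start)
            if shorter > 0 and overlap >= 0.5 * shorter:
                if hit.score > kept.score:
                    merged[i] = hit
                absorbed = True
                break
        if not absorbed:
            merged.append(hit)
    merged.sort(key=lambda h: h.target_start)
    return merged


def local_match(query_seq: str, target_seq: str, k: int = 20,
                scoring: tuple[int, int, int, int] = (1, -1, -4, -1)
                ) -> LocalHit | None:
    """Best gapped local alignment of ``query_seq`` against ``target_seq``.

    Both strands are searched; ``None`` when no k-mer seed exists.
    """
    match, mismatch, gap_open, gap_extend = scoring
    matcher = SeededLocalMatcher(k=k, match=match, mismatch=mismatch,
                                 gap_open=gap_open, gap_extend=gap_extend)
    return matcher.best(query_seq, target_seq)


# ---------------------------------------------------------------------------
# Relational match store

KEPT = "kept"
NO_MATCH = "no_match"
CONTIG_MULTI_LOCUS = "contig_multi_locus"
LOCUS_MULTI_CONTIG = "locus_multi_contig"


@dataclass
class MatchRecord:
    taxon: str
    locus_id: str
    contig_id: str
    orientation: str
    identity: float
    span: int
    kept: bool
    reason: str


@dataclass
class MatchStore:
    taxa: list[str] = field(default_factory=list)
    loci: list[str] = field(default_factory=list)
    matches: list[MatchRecord] = field(default_factory=list)
    sequences: dict[tuple[str, str], str] = field(default_factory=dict)
    # sequences maps (taxon, locus_id) -> orientation-normalized kept sequence

    def add_taxon_matches(self, taxon: str, records: list[MatchRecord],
                          sequences: dict[str, str] | None = None) -> None:
        if taxon not in self.taxa:
            self.taxa.append(taxon)
        for rec in records:
            if rec.locus_id and rec.locus_id not in self.loci:
                self.loci.append(rec.locus_id)
        self.matches.extend(records)
        if sequences:
            for locus_id, seq in sequences.items():
                self.sequences[(taxon, locus_id)] = seq

    def kept_matches(self) -> list[MatchRecord]:
        return [m for m in self.matches if m.kept]

    def kept_by_locus(self) -> dict[str, dict[str, MatchRecord]]:
        out: dict[str, dict[str, MatchRecord]] = {}
        for m in self.kept_matches():
            out.setdefault(m.locus_id, {})[m.taxon] = m
        return out

    def validate(self) -> None:
        taxa, loci = set(self.taxa), set(self.loci)
        seen_tl: set[tuple[str, str]] = set()
        seen_tc: set[tuple[str, str]] = set()
        for m in self.matches:
            if m.taxon not in taxa:
                raise ValueError(f"match references unknown taxon {m.taxon!r}")
            if m.locus_id and m.locus_id not in loci:
                raise ValueError(f"match references unknown locus {m.locus_id!r}")
            if m.kept:
                if (m.taxon, m.locus_id) in seen_tl:
                    raise ValueError(
                        f"two kept matches for {m.taxon}/{m.locus_id}")
                if (m.taxon, m.contig_id) in seen_tc:
                    raise ValueError(
                        f"two kept matches for contig {m.taxon}/{m.contig_id}")
                seen_tl.add((m.taxon, m.locus_id))
                seen_tc.add((m.taxon, m.contig_id))

    # deterministic 3-table serialization with a manifest
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_tsv([{"taxon": t} for t in sorted(self.taxa)],
                  directory / "taxa.tsv", ["taxon"])
        write_tsv([{"locus_id": l} for l in sorted(self.loci)],
                  directory / "loci.tsv", ["locus_id"])
        rows = sorted(
            ({"taxon": m.taxon, "locus_id": m.locus_id,
              "contig_id": m.contig_id, "orientation": m.orientation,
              "identity": f"{m.identity:.6f}", "span": m.span,
              "kept": int(m.kept), "reason": m.reason}
             for m in self.matches),
            key=lambda r: (r["taxon"], r["locus_id"], r["contig_id"]))
        write_tsv(rows, directory / "matches.tsv",
                  ["taxon", "locus_id", "contig_id", "orientation",
                   "identity", "span", "kept", "reason"])
        manifest = {"tables": ["taxa.tsv", "loci.tsv", "matches.tsv"],
                    "n_taxa": len(self.taxa), "n_loci": len(self.loci),
                    "n_matches": len(self.matches)}
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "MatchStore":
        import csv
        directory = Path(directory)
        store = cls()
        with open(directory / "taxa.tsv") as fh:
            store.taxa = [r["taxon"] for r in csv.DictReader(fh, delimiter="\t")]
        with open(directory / "loci.tsv") as fh:
            store.loci = [r["locus_id"] for r in csv.DictReader(fh, delimiter="\t")]
        with open(directory / "matches.tsv") as fh:
            for r in csv.DictReader(fh, delimiter="\t"):
                store.matches.append(MatchRecord(
                    taxon=r["taxon"], locus_id=r["locus_id"],
                    contig_id=r["contig_id"], orientation=r["orientation"],
                    identity=float(r["identity"]), span=int(r["span"]),
                    kept=bool(int(r["kept"])), reason=r["reason"]))
        store.validate()
        return store


# ---------------------------------------------------------------------------
# Per-taxon matching with duplicate removal


def _best_locus_hits(contig_seq: str, probes_by_locus: dict[str, list],
                     matcher: SeededLocalMatcher, min_match_len: int,
                     min_identity: float) -> dict[str, LocalHit]:
    """Best qualifying hit per locus for one contig (any probe counts)."""
    hits: dict[str, LocalHit] = {}
    for locus_id, probes in probes_by_locus.items():
        best: LocalHit | None = None
        for probe in probes:
            hit = matcher.best(probe.seq, contig_seq)
            if hit is None:
                continue
            if hit.span < min_match_len or hit.identity < min_identity:
                continue
            if best is None or hit.score > best.score:
                best = hit
        if best is not None:
            hits[locus_id] = best
    return hits


def match_taxon(taxon: str, contigs: list[FastaRecord],
                probes_by_locus: dict[str, list],
                config: PipelineConfig | None = None,
                matcher: SeededLocalMatcher | None = None
                ) -> tuple[list[MatchRecord], dict[str, str]]:
    """Match one taxon's contigs to loci and drop duplicate hits.

    Non-reciprocal duplicates (one contig matching several loci) are removed
    first, leaving their loci available to other contigs; reciprocal
    duplicates (one locus matched by several remaining contigs) are then
    removed.  Returns the match records plus kept per-locus sequences,
    orientation-normalized to the probe strand.  The result is independent
    of contig input order.
    """
    config = config or PipelineConfig()
    matcher = matcher or SeededLocalMatcher()
    records: list[MatchRecord] = []
    contig_hits: dict[str, dict[str, LocalHit]] = {}
    contig_seqs: dict[str, str] = {}
    for contig in sorted(contigs, key=lambda c: c.id):
        if contig.id in contig_seqs:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        contig_seqs[contig.id] = contig.seq
        hits = _best_locus_hits(contig.seq, probes_by_locus, matcher,
                                config.min_match_len, config.min_identity)
        if not hits:
            records.append(MatchRecord(taxon, "", contig.id, "+", 0.0, 0,
                                       False, NO_MATCH))
        else:
            contig_hits[contig.id] = hits

    # stage 1: contigs hitting >= 2 loci are non-reciprocal duplicates
    surviving: dict[str, dict[str, LocalHit]] = {}
    for contig_id in sorted(contig_hits):
        hits = contig_hits[contig_id]
        if len(hits) >= 2:
            for locus_id in sorted(hits):
                hit = hits[locus_id]
                records.append(MatchRecord(taxon, locus_id, contig_id,
                                           hit.orientation, hit.identity,
                                           hit.span, False,
                                           CONTIG_MULTI_LOCUS))
        else:
            surviving[contig_id] = hits

    # stage 2: loci hit by >= 2 surviving contigs are reciprocal duplicates
    locus_contigs: dict[str, list[str]] = {}
    for contig_id in sorted(surviving):
        (locus_id,) = surviving[contig_id]
        locus_contigs.setdefault(locus_id, []).append(contig_id)

    sequences: dict[str, str] = {}
    for locus_id in sorted(locus_contigs):
        contig_ids = locus_contigs[locus_id]
        is_dup = len(contig_ids) >= 2
        for contig_id in contig_ids:
            hit = surviving[contig_id][locus_id]
            records.append(MatchRecord(
                taxon, locus_id, contig_id, hit.orientation, hit.identity,
                hit.span, not is_dup,
                LOCUS_MULTI_CONTIG if is_dup else KEPT))
            if not is_dup:
                seq = contig_seqs[contig_id]
                sequences[locus_id] = seq if hit.orientation == "+" else revcomp(seq)
    return records, sequences


def harvest_from_genome(taxon: str, genome: dict[str, str],
                        probes_by_locus: dict[str, list],
                        flank: int = 500,
                        config: PipelineConfig | None = None,
                        matcher: SeededLocalMatcher | None = None
                        ) -> tuple[list[MatchRecord], dict[str, str]]:
    """Extract locus sequences from an assembled genome, as for an outgroup.

    For each locus, qualifying hits of its probes are merged into genomic
    sites; loci with exactly one site yield the matched span plus ``flank``
    bp each side (clipped at sequence ends), loci with several sites are
    dropped as duplicates.  Kept slices are normalized to the probe strand.
    """
    config = config or PipelineConfig()
    matcher = matcher or SeededLocalMatcher()
    records: list[MatchRecord] = []
    sequences: dict[str, str] = {}
    for locus_id in sorted(probes_by_locus):
        sites: list[tuple[str, LocalHit]] = []
        for probe in probes_by_locus[locus_id]:
            for chrom in sorted(genome):
                for hit in matcher.find_all(probe.seq, genome[chrom]):
                    if (hit.span >= config.min_match_len
                            and hit.identity >= config.min_identity):
                        sites.append((chrom, hit))
        merged = _merge_sites(sites)
        if not merged:
            continue
        if len(merged) >= 2:
            for chrom, hit in merged:
                records.append(MatchRecord(
                    taxon, locus_id, f"{chrom}:{hit.target_start}",
                    hit.orientation, hit.identity, hit.span, False,
                    LOCUS_MULTI_CONTIG))
            continue
        chrom, hit = merged[0]
        start = max(0, hit.target_start - flank)
        end = min(len(genome[chrom]), hit.target_end + flank)
        truncated = (start == 0 and hit.target_start - flank < 0) or \
                    (end == len(genome[chrom]) and hit.target_end + flank > end)
        slice_id = f"{chrom}:{start}-{end}" + ("|truncated" if truncated else "")
        records.append(MatchRecord(taxon, locus_id, slice_id, hit.orientation,
                                   hit.identity, hit.span, True, KEPT))
        seq = genome[chrom][start:end]
        sequences[locus_id] = seq if hit.orientation == "+" else revcomp(seq)
    return records, sequences


def _merge_sites(sites: list[tuple[str, LocalHit]]
                 ) -> list[tuple[str, LocalHit]]:
    """Merge per-probe hits of one locus into distinct genomic sites."""
    by_chrom: dict[str, list[LocalHit]] = {}
    for chrom, hit in sites:
        by_chrom.setdefault(chrom, []).append(hit)
    merged: list[tuple[str, LocalHit]] = []
    for chrom in sorted(by_chrom):
        hits = sorted(by_chrom[chrom], key=lambda h: h.target_start)
        cluster = [hits[0]]
        for hit in hits[1:]:
            # probes of one locus tile within ~buffer_len of each other
            if hit.target_start <= max(h.target_end for h in cluster) + 200:
                cluster.append(hit)
            else:
                merged.append((chrom, _site_envelope(cluster)))
                cluster = [hit]
        merged.append((chrom, _site_envelope(cluster)))
    return merged


def _site_envelope(cluster: list[LocalHit]) -> LocalHit:
    best = max(cluster, key=lambda h: h.score)
    return LocalHit(score=best.score, identity=best.identity,
                    span=best.span, orientation=best.orientation,
                    target_start=min(h.target_start for h in cluster),
                    target_end=max(h.target_end for h in cluster),
                    query_start=best.query_start, query_end=best.query_end)
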