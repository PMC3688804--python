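"""Locus selection, per-locus alignment, edge trimming, and concatenation.

Loci are selected from the match store by taxon-count and required-taxon
criteria, aligned (external command template, e.g. MAFFT, or a builtin
progressive aligner), edge-trimmed, and concatenated into an incomplete
supermatrix with partition definitions.  Missing data is '?' in the
supermatrix and '-' within locus alignments.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner

from .io import FastaRecord, read_fasta, write_fasta
from .matching import MatchStore


class AlignmentError(ValueError):
    pass


class EmptyAlignment(Exception):
    """Signals a locus alignment fully consumed by trimming."""


@dataclass
class LocusAlignment:
    locus_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"locus {self.locus_id}: rows differ in length {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.rows.values()]


@dataclass
class SupermatrixBundle:
    rows: dict[str, str]
    partitions: dict[str, tuple[str, list[tuple[int, int]]]]
    # partition name -> (model, [(start, end)] 0-based half-open)
    locus_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


# ---------------------------------------------------------------------------
# Locus selection


def select_loci(store: MatchStore, min_taxa: int = 3,
                required_taxa: list[str] | None = None,
                min_len: int = 0) -> list[str]:
    """Loci with enough kept taxa, all required taxa, and long-enough rows.

    ``min_len`` applies to the shortest kept sequence of the locus (match
    span when sequences were not retained).
    """
    required = set(required_taxa or [])
    kept = store.kept_by_locus()
    selected: list[str] = []
    for locus_id in sorted(kept):
        taxa_matches = kept[locus_id]
        if len(taxa_matches) < min_taxa:
            continue
        if not required <= set(taxa_matches):
            continue
        lengths = []
        for taxon, match in taxa_matches.items():
            seq = store.sequences.get((taxon, locus_id))
            lengths.append(len(seq) if seq is not None else match.span)
        if min(lengths) < min_len:
            continue
        selected.append(locus_id)
    return selected


# ---------------------------------------------------------------------------
# Alignment: external hook + builtin progressive fallback

_NUC = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(_NUC)}


def align_locus(locus_id: str, seqs: dict[str, str], mode: str = "builtin",
                command_template: str = "mafft --quiet {infile}"
                ) -> LocusAlignment:
    """Align one locus's sequences.

    ``mode='external'`` shells out through ``command_template`` (``{infile}``
    is replaced with a FASTA path; aligned FASTA is read from stdout).
    ``mode='builtin'`` runs the internal progressive aligner: UPGMA guide
    tree on k-mer distances, then profile-profile global alignment with
    affine gaps.
    """
    if len(seqs) < 2:
        raise AlignmentError(f"locus {locus_id}: need >= 2 sequences")
    if mode == "external":
        return _align_external(locus_id, seqs, command_template)
    if mode == "builtin":
        return _align_builtin(locus_id, seqs)
    raise ValueError(f"unknown alignment mode {mode!r}")


def _align_external(locus_id: str, seqs: dict[str, str],
                    command_template: str) -> LocusAlignment:
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta([FastaRecord(t, s) for t, s in seqs.items()], infile)
        cmd = shlex.split(command_template.format(infile=str(infile)))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignmentError(
                f"external aligner failed for {locus_id}: {proc.stderr}")
        outfile = Path(tmp) / "out.fasta"
        outfile.write_text(proc.stdout)
        records = read_fasta(outfile)
    return LocusAlignment(locus_id,
                          {r.id: r.seq.upper() for r in records})


def _kmer_profile(seq: str, k: int = 6) -> dict[str, int]:
    seq = seq.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        counts[seq[i:i + k]] = counts.get(seq[i:i + k], 0) + 1
    return counts


def _kmer_distance(a: dict[str, int], b: dict[str, int]) -> float:
    shared = sum(min(a[k], b[k]) for k in a if k in b)
    denom = min(sum(a.values()), sum(b.values())) or 1
    return 1.0 - shared / denom


def _upgma_order(names: list[str], dist: np.ndarray) -> list:
    """UPGMA join order as a nested merge list [(i, j), ...]."""
    clusters = {i: [i] for i in range(len(names))}
    active = sorted(clusters)
    joins: list[tuple[int, int]] = []
    next_id = len(names)
    while len(active) > 1:
        pairs = [(d2, i, j) for ai, i in enumerate(active)
                 for j in active[ai + 1:]
                 for d2 in [_cluster_dist(clusters[i], clusters[j], dist)]]
        _, i, j = min(pairs, key=lambda t: (t[0], t[1], t[2]))
        joins.append((i, j))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        active = sorted(clusters)
        next_id += 1
    return joins


def _cluster_dist(a: list[int], b: list[int], dist: np.ndarray) -> float:
    return float(np.mean([dist[i, j] for i in a for j in b]))


def _pairwise_global(a: str, b: str) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(a.upper(), b.upper())[0]
    return _render_alignment(aln, a.upper(), b.upper())


def _render_alignment(aln, a: str, b: str) -> tuple[str, str]:
    """Reconstruct gapped rows from the alignment coordinate path."""
    ra: list[str] = []
    rb: list[str] = []
    coords = aln.coordinates
    for col in range(coords.shape[1] - 1):
        a0, b0 = coords[0, col], coords[1, col]
        a1, b1 = coords[0, col + 1], coords[1, col + 1]
        if a1 > a0 and b1 > b0:
            ra.append(a[a0:a1])
            rb.append(b[b0:b1])
        elif a1 > a0:
            ra.append(a[a0:a1])
            rb.append("-" * (a1 - a0))
        else:
            ra.append("-" * (b1 - b0))
            rb.append(b[b0:b1])
    return "".join(ra), "".join(rb)


def _profile_align(prof_a: list[str], prof_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap global profile-profile alignment (Gotoh), sum-of-pairs."""
    La, Lb = len(prof_a[0]), len(prof_b[0])
    freq_a = _column_freqs(prof_a)
    freq_b = _column_freqs(prof_b)
    # column-column score: expected match(+1)/mismatch(-1) over residue pairs
    match = freq_a @ freq_b.T                    # P(same base) terms need care
    same = np.einsum("ik,jk->ij", freq_a, freq_b)
    occ_a = freq_a.sum(axis=1, keepdims=True)
    occ_b = freq_b.sum(axis=1, keepdims=True)
    pair_any = occ_a @ occ_b.T
    score = 2.0 * same - pair_any                # same*(+1) + (any-same)*(-1)

    go, ge = -4.0, -1.0
    neg = -1e18
    M = np.full((La + 1, Lb + 1), neg)
    X = np.full((La + 1, Lb + 1), neg)  # gap in profile b (consume a)
    Y = np.full((La + 1, Lb + 1), neg)  # gap in profile a (consume b)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, Lb + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, La + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        srow = score[i - 1]
        Xi[1:] = np.maximum(Mi1[1:] + go, Xi1[1:] + ge)
        Xi[0] = max(Mi1[0] + go, Xi1[0] + ge)
        best_prev = np.maximum(np.maximum(Mi1[:-1], Xi1[:-1]), Yi1[:-1])
        Mi[1:] = best_prev + srow
        # Y must be filled left-to-right (depends on same row)
        for j in range(1, Lb + 1):
            Yi[j] = max(Mi[j - 1] + go, Yi[j - 1] + ge, Xi[j - 1] + go)
    # traceback
    out_a: list[list[str]] = [[] for _ in prof_a]
    out_b: list[list[str]] = [[] for _ in prof_b]
    i, j = La, Lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - score[i - 1, j - 1]
            state = _match_state(prev, target)
            i, j = i - 1, j - 1
        elif (state == 1 and i > 0) or (j == 0 and i > 0):
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r in range(len(prof_b)):
                out_b[r].append("-")
            if j == 0:
                state = 1
            else:
                state = 0 if abs(X[i, j] - (M[i - 1, j] + go)) < 1e-9 else 1
            i -= 1
        else:
            for r in range(len(prof_a)):
                out_a[r].append("-")
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            if i == 0:
                state = 2
            else:
                if abs(Y[i, j] - (M[i, j - 1] + go)) < 1e-9:
                    state = 0
                elif abs(Y[i, j] - (X[i, j - 1] + go)) < 1e-9:
                    state = 1
                else:
                    state = 2
            j -= 1
    return (["".join(reversed(r)) for r in out_a],
            ["".join(reversed(r)) for r in out_b])


def _match_state(prev: list[float], target: float) -> int:
    for s, val in enumerate(prev):
        if abs(val - target) < 1e-9:
            return s
    return int(np.argmax(prev))


def _column_freqs(profile: list[str]) -> np.ndarray:
    L = len(profile[0])
    freq = np.zeros((L, 4))
    for row in profile:
        for i, c in enumerate(row.upper()):
            idx = _NUC_INDEX.get(c)
            if idx is not None:
                freq[i, idx] += 1
    return freq / len(profile)


def _align_builtin(locus_id: str, seqs: dict[str, str]) -> LocusAlignment:
    names = list(seqs)
    if len(names) == 2:
        a, b = _pairwise_global(seqs[names[0]], seqs[names[1]])
        return LocusAlignment(locus_id, {names[0]: a, names[1]: b})
    profiles = {i: [seqs[n].upper()] for i, n in enumerate(names)}
    members = {i: [n] for i, n in enumerate(names)}
    kprofs = [_kmer_profile(seqs[n]) for n in names]
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(kprofs[i], kprofs[j])
    joins = _upgma_order(names, dist)
    next_id = n
    for i, j in joins:
        pa, pb = _profile_align(profiles.pop(i), profiles.pop(j))
        profiles[next_id] = pa + pb
        members[next_id] = members.pop(i) + members.pop(j)
        next_id += 1
    (final_id,) = profiles
    rows = dict(zip(members[final_id], profiles[final_id]))
    return LocusAlignment(locus_id, {n: rows[n] for n in names})


# ---------------------------------------------------------------------------
# Edge trimming


def _column_stats(aln: LocusAlignment, i: int) -> tuple[float, float]:
    """(occupancy, identity) of column i; identity 1.0 with <= 1 residue."""
    col = aln.column(i)
    residues = [c.upper() for c in col if c not in "-?"]
    occupancy = len(residues) / len(col)
    if len(residues) <= 1:
        return occupancy, 1.0
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    return occupancy, max(counts.values()) / len(residues)


def trim_edges(aln: LocusAlignment, window: int = 20,
               min_occupancy: float = 0.5, min_edge_identity: float = 0.65,
               min_remaining_fraction: float = 0.25) -> LocusAlignment:
    """Trim ragged alignment edges and drop excessively trimmed taxa.

    Columns are removed from each edge until ``window`` consecutive columns
    each reach the occupancy and identity floors; taxa left with less than
    ``min_remaining_fraction`` of the trimmed length as residues are
    dropped, and all-gap columns are purged.  Raises :class:`EmptyAlignment`
    when nothing survives.  Idempotent.
    """
    L = aln.length
    good = [False] * L
    for i in range(L):
        occ, ident = _column_stats(aln, i)
        good[i] = occ >= min_occupancy and ident >= min_edge_identity
    eff_window = min(window, L)
    start = None
    for i in range(L - eff_window + 1):
        if all(good[i:i + eff_window]):
            start = i
            break
    if start is None:
        raise EmptyAlignment(aln.locus_id)
    end = None
    for j in range(L, eff_window - 1, -1):
        if all(good[j - eff_window:j]):
            end = j
            break
    if end is None or end <= start:
        raise EmptyAlignment(aln.locus_id)
    rows = {t: s[start:end] for t, s in aln.rows.items()}
    length = end - start
    rows = {t: s for t, s in rows.items()
            if sum(c not in "-?" for c in s) >= min_remaining_fraction * length}
    if len(rows) < 2:
        raise EmptyAlignment(aln.locus_id)
    keep_cols = [i for i in range(length)
                 if any(s[i] not in "-?" for s in rows.values())]
    if not keep_cols:
        raise EmptyAlignment(aln.locus_id)
    rows = {t: "".join(s[i] for i in keep_cols) for t, s in rows.items()}
    return LocusAlignment(aln.locus_id, rows)


# ---------------------------------------------------------------------------
# Concatenation and format emission


def concatenate(alns: list[LocusAlignment],
                partitions: dict[str, list[str]] | None = None,
                models: dict[str, str] | None = None) -> SupermatrixBundle:
    """Concatenate locus alignments into an incomplete supermatrix.

    Taxa missing from a locus are filled with '?'.  ``partitions`` maps
    partition name -> locus ids (default: one partition per locus);
    ``models`` maps partition name -> model name (default 'GTR').
    """
    taxa = sorted({t for aln in alns for t in aln.rows})
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    locus_ranges: dict[str, tuple[int, int]] = {}
    pos = 0
    for aln in alns:
        for t in taxa:
            pieces[t].append(aln.rows.get(t, "?" * aln.length))
        locus_ranges[aln.locus_id] = (pos, pos + aln.length)
        pos += aln.length
    if partitions is None:
        partitions = {aln.locus_id: [aln.locus_id] for aln in alns}
    part_defs: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for name in partitions:
        model = (models or {}).get(name, "GTR")
        ranges = [locus_ranges[lid] for lid in partitions[name]
                  if lid in locus_ranges]
        part_defs[name] = (model, sorted(ranges))
    return SupermatrixBundle(rows={t: "".join(pieces[t]) for t in taxa},
                             partitions=part_defs,
                             locus_ranges=locus_ranges)


def write_phylip(bundle: SupermatrixBundle, path: str | Path) -> None:
    """Relaxed PHYLIP: name, whitespace, full-length row."""
    rows = bundle.rows
    with open(path, "w") as fh:
        fh.write(f"{len(rows)} {bundle.length}\n")
        width = max(len(t) for t in rows) + 2
        for taxon in sorted(rows):
            fh.write(f"{taxon.replace(' ', '_'):<{width}}{rows[taxon]}\n")


def write_nexus(bundle: SupermatrixBundle, path: str | Path) -> None:
    rows = bundle.rows
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(rows)} nchar={bundle.length};\n")
        fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
        width = max(len(t) for t in rows) + 2
        for taxon in sorted(rows):
            fh.write(f"    {taxon.replace(' ', '_'):<{width}}{rows[taxon]}\n")
        fh.write("  ;\nend;\n\nbegin sets;\n")
        for name, (model, ranges) in bundle.partitions.items():
            spans = " ".join(f"{a + 1}-{b}" for a, b in ranges)
            fh.write(f"  charset {name} = {spans};\n")
        fh.write("end;\n")


def write_raxml_partitions(bundle: SupermatrixBundle, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (model, ranges) in bundle.partitions.items():
            spans = ", ".join(f"{a + 1}-{b}" for a, b in ranges)
            fh.write(f"DNA, {name} = {spans}\n")


def split_by_ranges(bundle: SupermatrixBundle
                    ) -> dict[str, dict[str, str]]:
    """Recover per-locus blocks column-for-column from the supermatrix."""
    out: dict[str, dict[str, str]] = {}
    for locus_id, (a, b) in bundle.locus_ranges.items():
        out[locus_id] = {t: s[a:b] for t, s in bundle.rows.items()}
    return out
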