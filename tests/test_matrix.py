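import numpy as np
import pytest

from uceflow.io import FastaRecord
from uceflow.matching import MatchRecord, MatchStore, match_taxon
from uceflow.matrix import (AlignmentError, EmptyAlignment, LocusAlignment,
                            align_locus, concatenate, select_loci,
                            split_by_ranges, trim_edges, write_nexus,
                            write_phylip, write_raxml_partitions)


def needleman_wunsch_score(a: str, b: str, match=1, mismatch=-1,
                           gap_open=-4, gap_extend=-1) -> float:
    """Exhaustive affine-gap global DP (first gap char -4, then -1)."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def _score_alignment(row_a: str, row_b: str) -> float:
    score, in_gap = 0.0, None
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            which = "a" if x == "-" else "b"
            score += -1 if in_gap == which else -4
            in_gap = which
        else:
            score += 1 if x == y else -1
            in_gap = None
    return score


def _store_with(loci_taxa: dict[str, dict[str, int]]) -> MatchStore:
    """Build a store from {locus: {taxon: span}}."""
    store = MatchStore()
    for locus, taxa in loci_taxa.items():
        for taxon, span in taxa.items():
            if taxon not in store.taxa:
                store.taxa.append(taxon)
            if locus not in store.loci:
                store.loci.append(locus)
            store.matches.append(MatchRecord(
                taxon, locus, f"{taxon}_{locus}", "+", 0.95, span,
                True, "kept"))
    return store


class TestSelectLoci:
    def test_min_taxa(self):
        store = _store_with({"L1": {"a": 200, "b": 200, "c": 200},
                             "L2": {"a": 200, "b": 200}})
        assert select_loci(store, min_taxa=3) == ["L1"]

    def test_required_taxa(self):
        store = _store_with({
            "L1": {"Polypterus": 200, "Acipenser": 200, "x": 200},
            "L2": {"Polypterus": 200, "x": 200, "y": 200}})
        assert select_loci(store, min_taxa=3,
                           required_taxa=["Polypterus", "Acipenser"]) == ["L1"]

    def test_min_length(self):
        store = _store_with({"L1": {"a": 49, "b": 200, "c": 200},
                             "L2": {"a": 50, "b": 200, "c": 200}})
        assert select_loci(store, min_taxa=3, min_len=50) == ["L2"]


class TestAlignLocus:
    def test_identical_sequences_no_gaps(self, random_seq):
        seq = random_seq(100)
        aln = align_locus("L", {"a": seq, "b": seq})
        assert aln.rows == {"a": seq, "b": seq}

    def test_single_deletion(self):
        aln = align_locus("L", {"a": "ACGTACGT", "b": "ACGACGT"})
        assert aln.length == 8
        assert aln.rows["b"].count("-") == 1
        assert aln.rows["a"] == "ACGTACGT"

    def test_single_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_locus("L", {"a": "ACGT"})

    def test_pairwise_equals_global_dp_optimum(self, rng, random_seq):
        """Builtin 2-sequence alignment scores exactly the affine NW optimum."""
        for _ in range(6):
            a = random_seq(int(rng.integers(30, 90)))
            # derive b by point edits so the pair is alignable
            b = list(a)
            for _ in range(int(rng.integers(1, 6))):
                op = rng.integers(0, 3)
                pos = int(rng.integers(0, len(b)))
                if op == 0:
                    b[pos] = "ACGT"[rng.integers(0, 4)]
                elif op == 1 and len(b) > 10:
                    del b[pos]
                else:
                    b.insert(pos, "ACGT"[rng.integers(0, 4)])
            b = "".join(b)
            aln = align_locus("L", {"a": a, "b": b})
            assert _score_alignment(aln.rows["a"], aln.rows["b"]) == \
                pytest.approx(needleman_wunsch_score(a, b))

    def test_builtin_handles_multiple_sequences(self, random_seq):
        base = random_seq(80)
        seqs = {"a": base, "b": base,
                "c": base[:40] + base[43:],        # 3-bp deletion
                "d": base[:20] + "T" + base[21:]}  # substitution
        aln = align_locus("L", seqs)
        lengths = {len(s) for s in aln.rows.values()}
        assert len(lengths) == 1
        assert aln.rows["a"].replace("-", "") == base

    def test_external_mafft_agrees_on_easy_case(self, random_seq):
        base = random_seq(120)
        seqs = {"a": base, "b": base, "c": base[:60] + base[62:]}
        builtin = align_locus("L", seqs, mode="builtin")
        external = align_locus("L", seqs, mode="external")
        assert {t: s.replace("-", "") for t, s in external.rows.items()} == seqs
        assert external.length in (builtin.length, builtin.length + 1,
                                   builtin.length - 1, 120)


class TestTrimEdges:
    def _ragged(self, random_seq):
        core = random_seq(80)
        rows = {}
        for i in range(5):
            lead = "-" * 10 if i > 0 else random_seq(10)
            tail = random_seq(10) if i < 2 else "-" * 10
            rows[f"t{i}"] = lead + core + tail
        return LocusAlignment("L", rows)

    def test_clean_alignment_unchanged(self, random_seq):
        seq = random_seq(60)
        aln = LocusAlignment("L", {"a": seq, "b": seq, "c": seq})
        out = trim_edges(aln)
        assert out.rows == aln.rows

    def test_low_occupancy_edges_removed(self, random_seq):
        aln = self._ragged(random_seq)
        out = trim_edges(aln, window=20, min_occupancy=0.5)
        assert out.length == 80
        for row in out.rows.values():
            assert "-" not in row[:1]  # edges now occupied

    def test_idempotent_and_never_grows(self, random_seq):
        aln = self._ragged(random_seq)
        once = trim_edges(aln)
        twice = trim_edges(once)
        assert once.rows == twice.rows
        for taxon in once.rows:
            assert sum(c != "-" for c in once.rows[taxon]) <= \
                sum(c != "-" for c in aln.rows[taxon])

    def test_overtrimmed_taxon_dropped(self, random_seq):
        core = random_seq(100)
        rows = {f"t{i}": core for i in range(4)}
        rows["sparse"] = core[:10] + "-" * 90
        out = trim_edges(LocusAlignment("L", rows),
                         min_remaining_fraction=0.25)
        assert "sparse" not in out.rows
        assert len(out.rows) == 4

    def test_hopeless_alignment_signals_empty(self, random_seq):
        rows = {"a": random_seq(30) + "-" * 30,
                "b": "-" * 30 + random_seq(30)}
        with pytest.raises(EmptyAlignment):
            trim_edges(LocusAlignment("L", rows), window=20,
                       min_occupancy=0.9)


class TestConcatenate:
    def test_lengths_add(self, random_seq):
        a1 = LocusAlignment("A", {"x": random_seq(100), "y": random_seq(100)})
        a2 = LocusAlignment("B", {"x": random_seq(50), "y": random_seq(50)})
        bundle = concatenate([a1, a2])
        assert bundle.length == 150

    def test_missing_taxon_filled_with_question_marks(self, random_seq):
        a1 = LocusAlignment("A", {"x": random_seq(100), "y": random_seq(100)})
        a2 = LocusAlignment("B", {"y": random_seq(50), "z": random_seq(50)})
        bundle = concatenate([a1, a2])
        assert bundle.rows["x"][100:] == "?" * 50
        assert bundle.rows["z"][:100] == "?" * 100

    def test_split_recovers_every_locus(self, rng, random_seq):
        lengths = rng.integers(40, 90, size=5)
        alns = [LocusAlignment(f"L{i}",
                               {t: random_seq(int(lengths[i]))
                                for t in ("a", "b", "c")})
                for i in range(5)]
        bundle = concatenate(alns)
        back = split_by_ranges(bundle)
        for aln in alns:
            for taxon, row in aln.rows.items():
                assert back[aln.locus_id][taxon] == row

    def test_partition_ranges_tile_matrix(self, random_seq):
        alns = [LocusAlignment(f"L{i}", {"a": random_seq(60),
                                         "b": random_seq(60)})
                for i in range(4)]
        bundle = concatenate(alns, partitions={"p1": ["L0", "L2"],
                                               "p2": ["L1", "L3"]})
        covered = sorted(r for _, ranges in bundle.partitions.values()
                         for r in ranges)
        assert covered == [(0, 60), (60, 120), (120, 180), (180, 240)]

    def test_emitted_files_parse(self, tmp_path, random_seq):
        alns = [LocusAlignment("L0", {"a": random_seq(30),
                                      "b": random_seq(30)}),
                LocusAlignment("L1", {"a": random_seq(20),
                                      "c": random_seq(20)})]
        bundle = concatenate(alns)
        write_phylip(bundle, tmp_path / "m.phy")
        write_nexus(bundle, tmp_path / "m.nex")
        write_raxml_partitions(bundle, tmp_path / "m.part")
        header = (tmp_path / "m.phy").read_text().splitlines()[0]
        assert header.split() == ["3", "50"]
        import dendropy
        mat = dendropy.DnaCharacterMatrix.get(path=str(tmp_path / "m.nex"),
                                              schema="nexus")
        assert len(mat) == 3
        part = (tmp_path / "m.part").read_text()
        assert "1-30" in part and "31-50" in part


class TestEndToEndMatrix:
    def test_matched_sequences_flow_into_supermatrix(self, random_seq):
        from uceflow.probes import probes_by_locus, tile_loci
        loci = {f"L{i}": random_seq(180) for i in range(2)}
        by_locus = probes_by_locus(tile_loci(loci))
        store = MatchStore()
        for taxon in ("t1", "t2", "t3"):
            contigs = [FastaRecord(f"{taxon}_{lid}",
                                   random_seq(40) + seq + random_seq(40))
                       for lid, seq in loci.items()]
            records, seqs = match_taxon(taxon, contigs, by_locus)
            store.add_taxon_matches(taxon, records, seqs)
        selected = select_loci(store, min_taxa=3)
        assert selected == ["L0", "L1"]
        alns = []
        for locus_id in selected:
            seqs = {t: store.sequences[(t, locus_id)]
                    for t in store.taxa}
            alns.append(align_locus(locus_id, seqs))
        bundle = concatenate(alns)
        assert set(bundle.rows) == {"t1", "t2", "t3"}
        assert bundle.length == sum(a.length for a in alns)
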