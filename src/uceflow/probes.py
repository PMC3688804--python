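"""Capture-probe tiling across buffered loci.

Probes of length ``probe_len`` (default 120 bp) are tiled at ``density``
per locus (default 4x) with evenly spread offsets, so a 180-bp locus gets
probes at offsets 0, 20, 40 and 60 and its central third is covered by all
four probes.
"""

from __future__ import annotations

from dataclasses import dataclass


class ProbeDesignError(ValueError):
    pass


@dataclass
class Probe:
    probe_id: str
    locus_id: str
    tile_index: int
    offset: int
    seq: str


def _round_half_up(x: float) -> int:
    import math
    return math.floor(x + 0.5)


def tile_locus(locus_id: str, locus_seq: str, probe_len: int = 120,
               density: int = 4) -> list[Probe]:
    """Tile ``density`` probes with evenly spread offsets across a locus.

    Offsets follow round(i * (L - p) / (density - 1)) for i in 0..density-1;
    when the locus equals the probe length (or density is 1) all offsets
    collapse to a single probe at 0.
    """
    L, p = len(locus_seq), probe_len
    if L < p:
        raise ProbeDesignError(
            f"locus {locus_id!r} ({L} bp) shorter than probe length {p}")
    if density < 1:
        raise ProbeDesignError("density must be >= 1")
    if density == 1 or L == p:
        offsets = [0]
    else:
        offsets = []
        for i in range(density):
            off = _round_half_up(i * (L - p) / (density - 1))
            if off not in offsets:
                offsets.append(off)
    return [
        Probe(probe_id=f"{locus_id}_p{i}", locus_id=locus_id, tile_index=i,
              offset=off, seq=locus_seq[off:off + p])
        for i, off in enumerate(offsets)
    ]


def tile_loci(loci: dict[str, str], probe_len: int = 120,
              density: int = 4) -> list[Probe]:
    probes: list[Probe] = []
    for locus_id in loci:
        probes.extend(tile_locus(locus_id, loci[locus_id], probe_len, density))
    return probes


def qc_probes(probes: list[Probe], max_masked_fraction: float = 0.25
              ) -> tuple[list[Probe], list[tuple[Probe, str]]]:
    """Split probes into (kept, rejected-with-reason).

    A probe is rejected if it contains any 'N' (reason ``has_n``) or if its
    soft-masked (lowercase) fraction exceeds ``max_masked_fraction``
    (reason ``masked``).
    """
    kept: list[Probe] = []
    rejected: list[tuple[Probe, str]] = []
    for probe in probes:
        if "N" in probe.seq.upper():
            rejected.append((probe, "has_n"))
            continue
        masked = sum(c.islower() for c in probe.seq) / len(probe.seq)
        if masked > max_masked_fraction:
            rejected.append((probe, "masked"))
            continue
        kept.append(probe)
    return kept, rejected


def probes_by_locus(probes: list[Probe]) -> dict[str, list[Probe]]:
    grouped: dict[str, list[Probe]] = {}
    for probe in probes:
        grouped.setdefault(probe.locus_id, []).append(probe)
    return grouped


def probe_fasta_records(probes: list[Probe]):
    from .io import FastaRecord
    return [FastaRecord(id=p.probe_id,
                        seq=p.seq,
                        description=f"|locus:{p.locus_id}|offset:{p.offset}")
            for p in probes]
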