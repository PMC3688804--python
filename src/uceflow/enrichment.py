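"""Per-taxon enrichment efficiency and cross-taxon aggregates.

On-target fractions measure how much of a sequencing library ended up in
enriched loci: ``contigs_on_target = uce_contigs / contigs_assembled`` and
``reads_on_target = reads_in_uce_contigs / trimmed_reads``.  Aggregates
report the per-column mean, a 95% normal CI half-width (1.96 s / sqrt(n),
sample standard deviation), and min/max.  All arithmetic is full precision;
rounding — half away from zero — happens only at the reporting layer
(integers for counts and coverage, two decimals for fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TaxonEnrichmentRow:
    taxon: str
    trimmed_reads: int
    contigs_assembled: int
    reads_in_contigs: int
    uce_contigs: int
    reads_in_uce_contigs: int
    avg_uce_contig_size: float
    avg_coverage: float
    contigs_on_target: float
    reads_on_target: float

    def report(self) -> dict:
        """Reporting view with fractions rounded half-up to 2 decimals."""
        return {
            "taxon": self.taxon,
            "trimmed_reads": self.trimmed_reads,
            "contigs_assembled": self.contigs_assembled,
            "reads_in_contigs": self.reads_in_contigs,
            "uce_contigs": self.uce_contigs,
            "reads_in_uce_contigs": self.reads_in_uce_contigs,
            "avg_size": self.avg_uce_contig_size,
            "avg_coverage": self.avg_coverage,
            "contigs_on_target": round_half_up(self.contigs_on_target, 2),
            "reads_on_target": round_half_up(self.reads_on_target, 2),
        }


def per_taxon_stats(row: dict) -> TaxonEnrichmentRow:
    """Derive on-target fractions for one taxon's count record."""
    for key in ("trimmed_reads", "contigs_assembled", "reads_in_contigs",
                "uce_contigs", "reads_in_uce_contigs"):
        if row[key] < 0:
            raise ValueError(f"{key} is negative for {row.get('taxon')}")
    if row["contigs_assembled"] == 0 or row["trimmed_reads"] == 0:
        raise ZeroDivisionError(
            f"zero denominator for taxon {row.get('taxon')!r}")
    if row["uce_contigs"] > row["contigs_assembled"]:
        raise ValueError("more UCE contigs than assembled contigs")
    if not (row["reads_in_uce_contigs"] <= row["reads_in_contigs"]
            <= row["trimmed_reads"]):
        raise ValueError("read counts are not nested")
    return TaxonEnrichmentRow(
        taxon=row["taxon"],
        trimmed_reads=row["trimmed_reads"],
        contigs_assembled=row["contigs_assembled"],
        reads_in_contigs=row["reads_in_contigs"],
        uce_contigs=row["uce_contigs"],
        reads_in_uce_contigs=row["reads_in_uce_contigs"],
        avg_uce_contig_size=row.get("avg_size", float("nan")),
        avg_coverage=row.get("avg_coverage", float("nan")),
        contigs_on_target=row["uce_contigs"] / row["contigs_assembled"],
        reads_on_target=row["reads_in_uce_contigs"] / row["trimmed_reads"],
    )


_COUNT_COLS = ("trimmed_reads", "contigs_assembled", "reads_in_contigs",
               "uce_contigs", "reads_in_uce_contigs")
_FOLD_COLS = ("avg_uce_contig_size", "avg_coverage")
_FRACTION_COLS = ("contigs_on_target", "reads_on_target")


def aggregate(rows: list[TaxonEnrichmentRow]) -> dict[str, dict[str, float]]:
    """Full-precision column summaries: mean, 95% CI half-width, min, max."""
    if len(rows) < 2:
        raise ValueError("aggregation needs at least 2 rows")
    out: dict[str, dict[str, float]] = {}
    n = len(rows)
    for col in _COUNT_COLS + _FOLD_COLS + _FRACTION_COLS:
        values = [getattr(r, col) for r in rows]
        mean = sum(values) / n
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        out[col] = {
            "mean": mean,
            "ci95_half_width": 1.96 * math.sqrt(var) / math.sqrt(n),
            "min": min(values),
            "max": max(values),
        }
    return out


def format_aggregate(agg: dict[str, dict[str, float]]
                     ) -> dict[str, dict[str, float]]:
    """Reporting rounding: counts/fold to integers, fractions to 2 decimals;
    CI half-widths to 2 decimals for fractions, integers otherwise."""
    out: dict[str, dict[str, float]] = {}
    for col, stats in agg.items():
        decimals = 2 if col in _FRACTION_COLS else 0
        out[col] = {
            "mean": round_half_up(stats["mean"], decimals),
            "ci95_half_width": round_half_up(stats["ci95_half_width"],
                                             2 if col in _FRACTION_COLS else 0),
            "min": round_half_up(stats["min"], decimals),
            "max": round_half_up(stats["max"], decimals),
        }
    return out


def table_rows(table: list[dict]) -> list[TaxonEnrichmentRow]:
    return [per_taxon_stats(row) for row in table]


# ---------------------------------------------------------------------------
# Alignment-matrix bookkeeping


def mean_locus_length(total_characters: int, locus_count: int) -> int:
    """Mean locus length, rounded half-up to the nearest base."""
    if locus_count <= 0:
        raise ValueError("locus count must be positive")
    return int(round_half_up(total_characters / locus_count))


def matrix_stats(alignments) -> dict[str, float]:
    """Locus count, total characters, mean length, and taxa-per-locus stats."""
    if not alignments:
        raise ValueError("no alignments")
    lengths = [aln.length for aln in alignments]
    taxa_counts = [len(aln.rows) for aln in alignments]
    total = sum(lengths)
    return {
        "locus_count": len(alignments),
        "total_characters": total,
        "mean_length": mean_locus_length(total, len(alignments)),
        "mean_taxa_per_locus": round_half_up(
            sum(taxa_counts) / len(taxa_counts)),
        "min_taxa": min(taxa_counts),
        "max_taxa": max(taxa_counts),
    }
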