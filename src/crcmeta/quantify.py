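"""Read-mapping quantification: two-step unique/multi-mapped redistribution.

Taxonomic profiles are built from reads mapped against a marker-gene
database.  Each read contributes nucleotide counts equal to its length.
Uniquely mapping reads are assigned first; reads mapping to several taxa
with the same (best) alignment score are then split among those taxa in
proportion to the taxa's unique counts.  Counts are finally marker-length
normalized and turned into relative abundances whose denominator includes
the unmapped remainder, so per-sample abundances sum to <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParseError


@dataclass
class ReadMapping:
    """One read and its candidate taxa.

    ``candidates`` is a list of ``(taxon_id, alignment_score)``; before
    counting, candidates are reduced to the best-score ties only.
    """

    read_id: str
    read_length: float
    candidates: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise DataError(f"read {self.read_id!r}: read_length must be > 0")
        if not self.candidates:
            raise DataError(f"read {self.read_id!r}: empty candidate list")
        if not all(np.isfinite(s) for _, s in self.candidates):
            raise DataError(f"read {self.read_id!r}: non-finite alignment score")

    def best_candidates(self) -> list[str]:
        """Taxa tied at the best alignment score (deduplicated, input order)."""
        best = max(s for _, s in self.candidates)
        seen, out = set(), []
        for t, s in self.candidates:
            if s == best and t not in seen:
                seen.add(t)
                out.append(t)
        return out


@dataclass
class TaxonCounts:
    """Per-taxon nucleotide counts plus the bookkeeping for normalization."""

    counts: dict[str, float]
    lengths: dict[str, float] = field(default_factory=dict)
    total_sample_reads: int = 0
    mapped_reads: int = 0
    mapped_nucleotides: float = 0.0

    def __post_init__(self) -> None:
        for t, c in self.counts.items():
            if c < 0:
                raise DataError(f"negative count for taxon {t!r}")
        for t, c in self.counts.items():
            if c > 0 and t in self.lengths and self.lengths[t] <= 0:
                raise DataError(f"taxon {t!r} has nonzero count but length <= 0")


def two_step_counts(mappings: list[ReadMapping]) -> TaxonCounts:
    """Assign nucleotide counts to taxa in two steps.

    Step 1: every uniquely mapping read contributes its full length to its
    taxon.  Step 2: each multi-mapped read's length is split among its tied
    candidates proportionally to their step-1 unique counts; when no
    candidate has unique support the split is uniform, so the total
    assigned nucleotides always equal the summed read lengths.
    """
    counts: dict[str, float] = {}
    unique: dict[str, float] = {}
    multi: list[tuple[float, list[str]]] = []
    total_nt = 0.0
    for m in mappings:
        cands = m.best_candidates()
        total_nt += m.read_length
        if len(cands) == 1:
            unique[cands[0]] = unique.get(cands[0], 0.0) + m.read_length
        else:
            multi.append((m.read_length, cands))
    counts.update(unique)
    for length, cands in multi:
        support = np.array([unique.get(t, 0.0) for t in cands])
        total = support.sum()
        shares = support / total if total > 0 else np.full(len(cands), 1.0 / len(cands))
        for t, sh in zip(cands, shares):
            counts[t] = counts.get(t, 0.0) + length * sh
    return TaxonCounts(
        counts=counts,
        total_sample_reads=len(mappings),
        mapped_reads=len(mappings),
        mapped_nucleotides=total_nt,
    )


def counts_to_relative_abundance(counts: TaxonCounts) -> tuple[pd.Series, float]:
    """Length-normalized relative abundances, unmapped remainder included.

    Each taxon's signal is ``nucleotides / marker length``.  Unmapped reads
    (``total_sample_reads - mapped_reads``) enter the denominator as
    read-equivalent units: ``unmapped x mean read length / mean marker
    length``, so a sample's abundances sum to ``1 - remainder``.

    Returns the abundance Series and the unassigned remainder fraction.
    """
    if counts.total_sample_reads <= 0:
        raise DataError("total_sample_reads must be > 0")
    taxa = sorted(counts.counts)
    missing = [t for t in taxa if counts.counts[t] > 0 and t not in counts.lengths]
    if missing:
        raise DataError(f"missing marker length for taxa: {missing[:5]}")
    normed = np.array(
        [counts.counts[t] / counts.lengths[t] if counts.counts[t] > 0 else 0.0 for t in taxa]
    )
    unmapped_reads = counts.total_sample_reads - counts.mapped_reads
    if unmapped_reads < 0:
        raise DataError("total_sample_reads must be >= mapped reads")
    if unmapped_reads and counts.mapped_reads:
        mean_read_len = counts.mapped_nucleotides / counts.mapped_reads
        mean_marker_len = float(np.mean([counts.lengths[t] for t in taxa])) if taxa else 1.0
        remainder_units = unmapped_reads * mean_read_len / mean_marker_len
    elif unmapped_reads:
        remainder_units = float(unmapped_reads)
    else:
        remainder_units = 0.0
    denom = normed.sum() + remainder_units
    if denom <= 0:
        raise DataError("no signal: all counts zero and no unmapped reads")
    ab = pd.Series(normed / denom, index=taxa)
    return ab, remainder_units / denom


def read_mapping_table(path) -> list[ReadMapping]:
    """Parse a minimal mapping TSV: read_id, read_length, taxon_id, score.

    Rows sharing a read_id are one read's candidate list; the reader
    reduces candidates to best-score ties.
    """
    rows: dict[str, ReadMapping] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["read_id", "read_length", "taxon_id", "score"]
        if header != expected:
            raise ParseError(f"line 1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            rid, rlen, taxon, score = parts
            try:
                rlen_f, score_f = float(rlen), float(score)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric value ({exc})") from exc
            if rid in rows:
                if rows[rid].read_length != rlen_f:
                    raise ParseError(f"line {lineno}: read {rid!r} length mismatch")
                rows[rid].candidates.append((taxon, score_f))
            else:
                rows[rid] = ReadMapping(rid, rlen_f, [(taxon, score_f)])
    out = []
    for m in rows.values():
        best = m.best_candidates()
        out.append(ReadMapping(m.read_id, m.read_length, [(t, 0.0) for t in best]))
    return out
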