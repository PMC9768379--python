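"""Polymerase-free gap statistics on Miller chromatin spreads.

Miller spreads visualize every engaged Pol I complex on individual rDNA genes.
Because the polymerases are normally densely packed (~50 per gene), a long
polymerase-free stretch is the signature of an upstream complex having paused
while the downstream ones ran off.  This module quantifies such gaps from
digitized per-gene polymerase position lists:

* ``call_gaps`` — complement of the polymerase footprints within a gene;
* ``large_gap_filter`` — keep gaps long enough to accommodate ~40 packed
  polymerases (by default >25% of the gene; the alternative >23% preset used
  in some reports is exposed via ``threshold_fraction``);
* ``bin_gap_starts`` — frequency of large-gap start sites (promoter-proximal
  edges) in 10%-of-gene bins, reported at bin midpoints;
* ``summarize_gap_frequency`` — fraction of genes carrying at least one large
  gap.

A structural consequence of the large-gap definition: a gap longer than a
fraction ``t`` of the gene cannot start beyond ``1 - t`` of the gene, so the
3'-most bins are empty by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class MillerSpreadSet:
    """Digitized Miller-spread observations: one position list per gene.

    Positions are active-site coordinates (nt from the promoter); each
    polymerase occupies ``footprint`` nt centered on its position, so within a
    gene consecutive positions must differ by at least ``footprint``.
    """

    gene_length: float
    genes: list[np.ndarray]
    footprint: float

    def __post_init__(self) -> None:
        checked = []
        for i, pos in enumerate(self.genes):
            arr = np.asarray(pos, dtype=float)
            if arr.size:
                if np.any(np.diff(arr) < 0):
                    raise ValueError(f"gene {i}: positions not sorted")
                if arr[0] < 0 or arr[-1] >= self.gene_length:
                    raise ValueError(f"gene {i}: positions outside [0, gene_length)")
                if arr.size > 1 and np.any(np.diff(arr) < self.footprint):
                    raise ValueError(f"gene {i}: polymerases closer than footprint")
            checked.append(arr)
        self.genes = checked

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Gap:
    """A polymerase-free interval; ``start`` is its promoter-proximal edge."""

    gene_id: str
    start: float
    length: float
    gene_length: float

    @property
    def start_fraction(self) -> float:
        return self.start / self.gene_length


@dataclass(frozen=True)
class GapSummary:
    n_genes: int
    n_genes_with_large_gap: int
    fraction: float
    bin_midpoints: np.ndarray
    bin_frequencies: np.ndarray


def call_gaps(
    positions: Sequence[float],
    gene_length: float,
    footprint: float,
    gene_id: str = "gene",
) -> list[Gap]:
    """Polymerase-free intervals of a gene, as the complement of footprints.

    Each polymerase blocks ``[p - footprint/2, p + footprint/2]`` (clipped to
    the gene).  A gene with zero polymerases yields one gap spanning the whole
    gene with start 0.  Zero-length intervals are not reported.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size and np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    if pos.size and (pos[0] < 0 or pos[-1] >= gene_length):
        raise ValueError("positions outside [0, gene_length)")
    half = footprint / 2.0
    gaps: list[Gap] = []
    prev_end = 0.0
    for p in pos:
        s = max(p - half, 0.0)
        if s > prev_end:
            gaps.append(Gap(gene_id, prev_end, s - prev_end, gene_length))
        prev_end = max(prev_end, min(p + half, gene_length))
    if gene_length > prev_end:
        gaps.append(Gap(gene_id, prev_end, gene_length - prev_end, gene_length))
    return gaps


def large_gap_filter(
    gaps: Iterable[Gap],
    gene_length: float,
    threshold_fraction: float = 0.25,
) -> list[Gap]:
    """Keep gaps strictly longer than ``threshold_fraction`` of the gene."""
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    cut = threshold_fraction * gene_length
    return [g for g in gaps if g.length > cut]


def bin_gap_starts(
    large_gaps: Sequence[Gap],
    gene_length: float,
    n_bins: int = 10,
    n_scored: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency of gap start sites per bin of ``1/n_bins`` of the gene.

    Bin index is ``floor(start_fraction * n_bins)`` clamped to the last bin;
    frequencies are counts divided by ``n_scored`` (defaults to the number of
    gaps).  Returns ``(bin_midpoints_as_gene_fraction, frequencies)``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts = np.zeros(n_bins, dtype=float)
    for g in large_gaps:
        idx = min(int(g.start / gene_length * n_bins), n_bins - 1)
        counts[idx] += 1
    denom = n_scored if n_scored is not None else max(len(large_gaps), 1)
    midpoints = (np.arange(n_bins) + 0.5) / n_bins
    return midpoints, counts / denom


def summarize_gap_frequency(
    spreads: MillerSpreadSet,
    threshold_fraction: float = 0.25,
    n_bins: int = 10,
) -> GapSummary:
    """Per-gene large-gap incidence plus start-site bin frequencies.

    ``fraction`` counts genes with at least one large gap (a gene is counted
    once however many large gaps it carries); bin frequencies are normalized
    by the total number of genes scored.
    """
    if spreads.n_genes < 1:
        raise ValueError("need at least one gene")
    all_large: list[Gap] = []
    n_with = 0
    for i, pos in enumerate(spreads.genes):
        gaps = call_gaps(pos, spreads.gene_length, spreads.footprint, gene_id=f"gene{i}")
        large = large_gap_filter(gaps, spreads.gene_length, threshold_fraction)
        if large:
            n_with += 1
            all_large.extend(large)
    midpoints, freqs = bin_gap_starts(
        all_large, spreads.gene_length, n_bins=n_bins, n_scored=spreads.n_genes
    )
    return GapSummary(
        n_genes=spreads.n_genes,
        n_genes_with_large_gap=n_with,
        fraction=n_with / spreads.n_genes,
        bin_midpoints=midpoints,
        bin_frequencies=freqs,
    )


def write_spreads(spreads: MillerSpreadSet, path: str) -> None:
    """TSV: gene_id, comma-separated positions, gene_length (+footprint header)."""
    with open(path, "w") as fh:
        fh.write(f"# footprint={spreads.footprint}\n")
        fh.write("gene_id\tpositions\tgene_length\n")
        for i, pos in enumerate(spreads.genes):
            joined = ",".join(f"{p:g}" for p in pos)
            fh.write(f"gene{i}\t{joined}\t{spreads.gene_length:g}\n")


def read_spreads(path: str, footprint: float | None = None) -> MillerSpreadSet:
    """Read the TSV written by :func:`write_spreads` (or hand-made data)."""
    header_fp = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "footprint=" in line:
                header_fp = float(line.split("footprint=")[1])
            elif not line.startswith("#"):
                break
    table = pd.read_csv(path, sep="\t", comment="#")
    genes = []
    gene_length = None
    for _, row in table.iterrows():
        raw = row["positions"]
        if isinstance(raw, str) and raw.strip():
            genes.append(np.array([float(x) for x in raw.split(",")]))
        else:
            genes.append(np.empty(0))
        gene_length = float(row["gene_length"])
    fp = footprint if footprint is not None else (header_fp if header_fp is not None else 0.0)
    return MillerSpreadSet(gene_length=gene_length, genes=genes, footprint=fp)


def gaps_table(gaps: Sequence[Gap]) -> pd.DataFrame:
    """Per-gap table (gene_id, start, length, start_fraction)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in gaps],
            "start": [g.start for g in gaps],
            "length": [g.length for g in gaps],
            "start_fraction": [g.start_fraction for g in gaps],
        }
    )
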