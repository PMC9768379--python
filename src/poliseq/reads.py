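"""Raw-read processing: UMI deduplication, adaptor trimming, 3'-end mapping.

The pipeline mirrors standard NET-Seq preprocessing (deduplicate -> trim ->
align -> normalize) but replaces a genome aligner with an exact single-locus
mapper: every analysis here lives on one rDNA reference, and a zero-mismatch
mapper is verifiable against a brute-force substring oracle.  Externally
produced per-position count tables can be loaded instead via
:func:`load_counts_table` when working with real alignments.

The accounting identity holds for every processed library:

    input_reads = duplicates_removed + discarded_no_adaptor
                  + unmapped + ambiguous + mapped
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .rdna import RDNATemplate


@dataclass
class OccupancyProfile:
    """Per-position 3'-end (last incorporated nucleotide) occupancy.

    ``counts`` sums to ``stats['mapped']``; ``normalized`` is counts per
    million template-mapped reads (CPM), so libraries of different depth are
    directly comparable and ``normalized.sum() == 1e6`` whenever any read
    mapped.
    """

    library_id: str
    strain: str
    counts: np.ndarray
    normalized: np.ndarray | None = None
    stats: dict = field(default_factory=dict)


def read_fastq_sequences(path: str) -> list[str]:
    """Read sequences (only) from a FASTQ file."""
    with open(path) as fh:
        return [seq for _title, seq, _qual in FastqGeneralIterator(fh)]


def deduplicate_umis(reads: Sequence[str], umi_len: int) -> tuple[list[str], int]:
    """Collapse reads identical in (UMI, full insert sequence); keep the first.

    Operates pre-trimming, i.e. the insert still carries the adaptor, matching
    sequence-level deduplication before alignment.  Idempotent.
    """
    kept: list[str] = []
    seen: set[str] = set()
    removed = 0
    for r in reads:
        if len(r) < umi_len:
            raise ValueError(f"read shorter than UMI length {umi_len}: {r!r}")
        if r in seen:
            removed += 1
        else:
            seen.add(r)
            kept.append(r)
    return kept, removed


def trim_adaptor(
    reads: Sequence[str],
    adaptor: str,
    min_overlap: int = 5,
    umi_len: int = 0,
) -> tuple[list[str], int]:
    """Strip the UMI prefix and the 3' adaptor suffix from each read.

    The longest read suffix exactly matching a prefix of the adaptor (length
    >= ``min_overlap``) is removed; reads with no such suffix are discarded and
    counted.  Returns ``(inserts, n_discarded)``.
    """
    if not adaptor:
        raise ValueError("adaptor must be nonempty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    inserts: list[str] = []
    discarded = 0
    for r in reads:
        body = r[umi_len:]
        kmax = min(len(body), len(adaptor))
        for k in range(kmax, min_overlap - 1, -1):
            if body.endswith(adaptor[:k]):
                inserts.append(body[: len(body) - k])
                break
        else:
            discarded += 1
    return inserts, discarded


def _kmer_end_index(sequence: str, k: int) -> dict[str, list[int]]:
    """Map each k-mer of the template to the 0-based end positions it spans."""
    index: dict[str, list[int]] = {}
    for i in range(len(sequence) - k + 1):
        index.setdefault(sequence[i : i + k], []).append(i + k - 1)
    return index


def map_three_prime_ends(
    inserts: Sequence[str],
    template: RDNATemplate,
    min_match: int = 18,
    library_id: str = "lib",
    strain: str = "",
) -> OccupancyProfile:
    """Exact single-locus mapping of insert 3' ends onto the template.

    The 3'-terminal ``min_match``-mer of each insert is looked up against the
    nontemplate strand; a candidate only counts if the full insert extends to
    an exact match (truncated inserts reaching the TSS included).  Unique hit
    -> the aligned 3'-end position is incremented; zero valid hits -> unmapped;
    several -> ambiguous (discarded).  Inserts shorter than ``min_match`` are
    unmapped, not an error.
    """
    if min_match < 12:
        raise ValueError("min_match must be >= 12")
    seq = template.sequence
    index = _kmer_end_index(seq, min_match)
    counts = np.zeros(template.length, dtype=np.int64)
    unmapped = ambiguous = mapped = 0
    for ins in inserts:
        n = len(ins)
        if n < min_match:
            unmapped += 1
            continue
        hits = index.get(ins[-min_match:])
        if not hits:
            unmapped += 1
            continue
        valid = [e for e in hits if e - n + 1 >= 0 and seq[e - n + 1 : e + 1] == ins]
        if len(valid) == 1:
            counts[valid[0]] += 1
            mapped += 1
        elif not valid:
            unmapped += 1
        else:
            ambiguous += 1
    stats = {"mapped": mapped, "unmapped": unmapped, "ambiguous": ambiguous}
    return OccupancyProfile(
        library_id=library_id, strain=strain, counts=counts, stats=stats
    )


def normalize_profile(profile: OccupancyProfile) -> OccupancyProfile:
    """Counts-per-million (CPM) normalization over template-mapped reads."""
    total = int(profile.counts.sum())
    if total == 0:
        raise ValueError("cannot normalize an all-zero profile")
    profile.normalized = profile.counts * (1e6 / total)
    return profile


def process_library(
    reads: Sequence[str],
    template: RDNATemplate,
    adaptor: str,
    umi_len: int = 8,
    min_overlap: int = 5,
    min_match: int = 18,
    library_id: str = "lib",
    strain: str = "",
) -> OccupancyProfile:
    """Full pipeline on raw read strings: dedup -> trim -> map -> normalize."""
    if not reads:
        raise ValueError("empty read set")
    deduped, removed = deduplicate_umis(reads, umi_len)
    inserts, no_adaptor = trim_adaptor(deduped, adaptor, min_overlap=min_overlap, umi_len=umi_len)
    profile = map_three_prime_ends(
        inserts, template, min_match=min_match, library_id=library_id, strain=strain
    )
    profile.stats.update(
        {
            "input_reads": len(reads),
            "duplicates_removed": removed,
            "discarded_no_adaptor": no_adaptor,
        }
    )
    return normalize_profile(profile)


def process_fastq(path: str, template: RDNATemplate, **kwargs) -> OccupancyProfile:
    """Convenience: :func:`process_library` on a FASTQ file."""
    return process_library(read_fastq_sequences(path), template, **kwargs)


# ---------------------------------------------------------------------------
# I/O surfaces


def profile_table(profile: OccupancyProfile, template: RDNATemplate) -> pd.DataFrame:
    """Tidy per-position table: position (1-based), region, base, count, CPM."""
    region_names = np.empty(template.length, dtype=object)
    for r in template.regions:
        region_names[r.start : r.end] = r.name
    return pd.DataFrame(
        {
            "position": np.arange(1, template.length + 1),
            "region": region_names,
            "base": list(template.sequence),
            "count": profile.counts,
            "normalized": profile.normalized
            if profile.normalized is not None
            else np.zeros(template.length),
        }
    )


def write_profile_table(
    profile: OccupancyProfile, template: RDNATemplate, path: str, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_id={profile.library_id}\n# strain={profile.strain}\n")
        for key, val in sorted(profile.stats.items()):
            fh.write(f"# stat:{key}={val}\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        profile_table(profile, template).to_csv(fh, sep="\t", index=False)


def load_profile_table(path: str) -> OccupancyProfile:
    """Reconstruct an OccupancyProfile from :func:`write_profile_table` output."""
    library_id, strain, stats = "lib", "", {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("library_id="):
                library_id = body.split("=", 1)[1]
            elif body.startswith("strain="):
                strain = body.split("=", 1)[1]
            elif body.startswith("stat:"):
                key, val = body[5:].split("=", 1)
                stats[key] = int(val)
    table = pd.read_csv(path, sep="\t", comment="#")
    profile = OccupancyProfile(
        library_id=library_id,
        strain=strain,
        counts=table["count"].to_numpy(dtype=np.int64),
        normalized=table["normalized"].to_numpy(dtype=float),
        stats=stats,
    )
    return profile


def load_counts_table(
    path: str, template: RDNATemplate, library_id: str = "lib", strain: str = ""
) -> OccupancyProfile:
    """Real-data adapter: a TSV with columns ``position`` (1-based) and
    ``count`` (e.g. exported from genome-coverage files) becomes a profile."""
    table = pd.read_csv(path, sep="\t", comment="#")
    counts = np.zeros(template.length, dtype=np.int64)
    pos = table["position"].to_numpy(dtype=int) - 1
    if pos.min() < 0 or pos.max() >= template.length:
        raise ValueError("positions outside template")
    np.add.at(counts, pos, table["count"].to_numpy(dtype=np.int64))
    profile = OccupancyProfile(
        library_id=library_id,
        strain=strain,
        counts=counts,
        stats={"mapped": int(counts.sum()), "unmapped": 0, "ambiguous": 0},
    )
    return normalize_profile(profile)


def write_bedgraph(profile: OccupancyProfile, template: RDNATemplate, path: str) -> None:
    """bedGraph of nonzero raw counts (0-based half-open intervals)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.library_id}"\n')
        for i in np.nonzero(profile.counts)[0]:
            fh.write(f"{template.name}\t{i}\t{i + 1}\t{profile.counts[i]}\n")


def write_stats_report(profile: OccupancyProfile, path: str) -> None:
    """Key-value accounting report for one library."""
    with open(path, "w") as fh:
        fh.write(f"library_id\t{profile.library_id}\nstrain\t{profile.strain}\n")
        for key, val in sorted(profile.stats.items()):
            fh.write(f"{key}\t{val}\n")


def accounting_identity_holds(profile: OccupancyProfile) -> bool:
    """input = duplicates + no-adaptor + unmapped + ambiguous + mapped."""
    s = profile.stats
    return s["input_reads"] == (
        s["duplicates_removed"]
        + s["discarded_no_adaptor"]
        + s["unmapped"]
        + s["ambiguous"]
        + s["mapped"]
    )
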