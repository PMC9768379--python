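"""Model of the rDNA transcription unit (35S pre-rRNA gene).

Yeast RNA polymerase I transcribes a single ~6.7 kb unit whose transcript is
processed into the mature 18S, 5.8S and 25S rRNAs; the external and internal
transcribed spacers (ETS1, ITS1, ITS2, ETS2) are removed co- and
post-transcriptionally.  Because the spacers are degraded quickly they are free
of mature-rRNA contamination in NET-Seq libraries, which makes them the clean
window onto nascent-transcript occupancy.  Every other module in this package
works in the coordinate system defined here.

Conventions
-----------
* Internal coordinates are 0-based, half-open.  Every user-facing *report*
  (tables, pause positions, the first-C position) is 1-based relative to the
  transcription start site, matching the "+56" style used for in vitro
  templates.
* ``sequence`` is the nontemplate (RNA-like) strand, so a NET-Seq read is a
  literal substring of it.
* The ~200 genomic tandem repeats are collapsed onto one template; libraries
  are modeled as independent draws from it.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPACER = "spacer"
MATURE = "mature"

BASE_ORDER = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASE_ORDER)}

#: (name, length, class, GC fraction) of the bundled synthetic reference.
#: Lengths are plausible yeast-like choices summing to 6,700 nt so that a
#: 10%-of-gene bin is 670 bp; they are not measured boundaries.  Spacers follow
#: the canonical ETS1-18S-ITS1-5.8S-ITS2-25S-ETS2 order.
DEFAULT_REGION_SPECS: tuple[tuple[str, int, str, float], ...] = (
    ("ETS1", 700, SPACER, 0.42),
    ("18S", 1800, MATURE, 0.45),
    ("ITS1", 360, SPACER, 0.40),
    ("5.8S", 160, MATURE, 0.46),
    ("ITS2", 230, SPACER, 0.42),
    ("25S", 3050, MATURE, 0.47),
    ("ETS2", 400, SPACER, 0.40),
)

#: Seed of the bundled default template.  Fixed: the default template plays the
#: role of a reference assembly and must be identical across runs.
DEFAULT_TEMPLATE_SEED = 20220


@dataclass(frozen=True)
class Region:
    """A named interval of the transcription unit, 0-based half-open."""

    name: str
    start: int
    end: int
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in (SPACER, MATURE):
            raise ValueError(f"region class must be {SPACER!r} or {MATURE!r}, got {self.cls!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region bounds [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RDNATemplate:
    """A single transcription unit: nontemplate-strand sequence plus regions.

    Regions must tile ``[0, len(sequence))`` without overlap or gaps, and the
    sequence must be strictly over {A,C,G,T}; ambiguous characters are rejected
    rather than masked because the PWM arithmetic downstream assumes a
    four-letter alphabet.
    """

    name: str
    sequence: str
    regions: tuple[Region, ...]
    _codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(BASE_ORDER)
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)!r}")
        if not self.regions:
            raise ValueError("template must have at least one region")
        regs = tuple(sorted(self.regions, key=lambda r: r.start))
        if regs[0].start != 0:
            raise ValueError(f"coverage gap at 0 (first region starts at {regs[0].start})")
        for prev, cur in zip(regs, regs[1:]):
            if cur.start > prev.end:
                raise ValueError(f"coverage gap at {prev.end}")
            if cur.start < prev.end:
                raise ValueError(f"region overlap at {cur.start}")
        if regs[-1].end != len(self.sequence):
            raise ValueError(
                f"regions end at {regs[-1].end} but sequence has length {len(self.sequence)}"
            )
        object.__setattr__(self, "regions", regs)
        codes = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8).copy()
        lut = np.zeros(128, dtype=np.uint8)
        for b, i in _BASE_TO_CODE.items():
            lut[ord(b)] = i
        object.__setattr__(self, "_codes", lut[codes])

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_codes(self) -> np.ndarray:
        """Sequence as uint8 codes with A=0, C=1, G=2, T=3."""
        return self._codes

    def positions_of_class(self, cls: str) -> np.ndarray:
        """Sorted 0-based positions belonging to regions of the given class."""
        parts = [np.arange(r.start, r.end) for r in self.regions if r.cls == cls]
        if not parts:
            return np.empty(0, dtype=int)
        return np.concatenate(parts)

    def region_by_name(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")


def region_of(template: RDNATemplate, position: int) -> Region:
    """Return the unique region containing a 0-based position.

    Boundaries follow the half-open convention: a position equal to a region
    boundary belongs to the downstream region.
    """
    if not (0 <= position < template.length):
        raise IndexError(f"position {position} outside [0, {template.length})")
    starts = [r.start for r in template.regions]
    i = bisect.bisect_right(starts, position) - 1
    return template.regions[i]


def first_c_position(template: RDNATemplate, from_pos: int = 0) -> int | None:
    """1-based TSS-relative position of the first C at or after ``from_pos``.

    With CTP withheld, elongation complexes synchronize at the first encoded C
    of the nontemplate strand; on a construct with a 55-nt C-less leader that
    is position +56.  Returns ``None`` if no C exists downstream.
    """
    idx = template.sequence.find("C", max(from_pos, 0))
    return None if idx == -1 else idx + 1


def to_one_based(position: int) -> int:
    """Convert an internal 0-based coordinate to a reported 1-based one."""
    return position + 1


def from_one_based(position: int) -> int:
    """Convert a reported 1-based coordinate to the internal 0-based one."""
    return position - 1


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(BASE_ORDER[c] for c in codes)


def make_default_template(
    seed: int = DEFAULT_TEMPLATE_SEED,
    region_lengths: Mapping[str, int] | None = None,
    gc: Mapping[str, float] | float | None = None,
    total_length: int | None = None,
    name: str = "rDNA-35S-synthetic",
) -> RDNATemplate:
    """Build the synthetic 6,700-nt reference transcription unit.

    The sequence is pseudo-random with per-region GC content; it stands in for
    a real 35S annotation (whose spacer/mature boundaries are not modeled
    here), with realistic region proportions.  Deterministic given ``seed``.

    Parameters
    ----------
    region_lengths
        Optional override of per-region lengths (name -> nt).  If
        ``total_length`` is given the override must sum to it.
    gc
        Per-region GC fractions (name -> fraction) or one global fraction.
    """
    lengths = {n: ln for n, ln, _, _ in DEFAULT_REGION_SPECS}
    if region_lengths is not None:
        lengths.update(region_lengths)
    if total_length is not None and sum(lengths.values()) != total_length:
        raise ValueError(
            f"region lengths sum to {sum(lengths.values())}, expected {total_length}"
        )
    gcs = {n: g for n, _, _, g in DEFAULT_REGION_SPECS}
    if isinstance(gc, Mapping):
        gcs.update(gc)
    elif gc is not None:
        gcs = {n: float(gc) for n in gcs}

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    regions: list[Region] = []
    cursor = 0
    for rname, _, cls, _ in DEFAULT_REGION_SPECS:
        ln = lengths[rname]
        parts.append(_random_sequence(rng, ln, gcs[rname]))
        regions.append(Region(rname, cursor, cursor + ln, cls))
        cursor += ln
    return RDNATemplate(name=name, sequence="".join(parts), regions=tuple(regions))


def make_cless_leader_template(
    seed: int = 0,
    leader_len: int = 55,
    length: int = 200,
    name: str = "invitro-cless-leader-synthetic",
) -> RDNATemplate:
    """Synthetic in-vitro-style construct: a C-less leader then normal sequence.

    The first ``leader_len`` nontemplate-strand bases are drawn from {A,G,T}
    and position ``leader_len + 1`` (1-based) is forced to C, emulating the
    promoter-proximal C-less cassette used to synchronize elongation complexes
    by CTP omission.
    """
    if length <= leader_len:
        raise ValueError("length must exceed leader_len")
    rng = np.random.default_rng(seed)
    leader = "".join(rng.choice(list("AGT"), size=leader_len))
    tail = _random_sequence(rng, length - leader_len - 1, gc=0.45)
    seq = leader + "C" + tail
    return RDNATemplate(
        name=name,
        sequence=seq,
        regions=(Region("construct", 0, length, SPACER),),
    )


def load_template(fasta_path: str, regions_path: str) -> RDNATemplate:
    """Load a template from a single-record FASTA plus a region TSV.

    The region table is BED-like with a header row and columns
    ``name, start, end, class`` (0-based half-open).
    """
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    table = pd.read_csv(regions_path, sep="\t", comment="#")
    required = {"name", "start", "end", "class"}
    if not required.issubset(table.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    regions = tuple(
        Region(str(row["name"]), int(row["start"]), int(row["end"]), str(row["class"]))
        for _, row in table.iterrows()
    )
    return RDNATemplate(name=rec.id, sequence=str(rec.seq).upper(), regions=regions)


def write_template(template: RDNATemplate, fasta_path: str, regions_path: str) -> None:
    """Write a template as single-record FASTA plus region TSV (round-trips)."""
    rec = SeqRecord(Seq(template.sequence), id=template.name, description="")
    SeqIO.write([rec], fasta_path, "fasta")
    table = pd.DataFrame(
        {
            "name": [r.name for r in template.regions],
            "start": [r.start for r in template.regions],
            "end": [r.end for r in template.regions],
            "class": [r.cls for r in template.regions],
        }
    )
    table.to_csv(regions_path, sep="\t", index=False)
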