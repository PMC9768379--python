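"""Pause-site calling and differential sequence logos.

Pause sites are the top-q% most occupied template positions (q = 2.5 by
default) within the spacer regions, called on the replicate-median profile of
each strain.  Around each pause site a sequence context is extracted over a
window of offsets relative to the last incorporated nucleotide (offset 0);
offsets <= 0 cover the RNA:DNA hybrid, positive offsets downstream DNA.

Strain preference differences are summarized DiffLogo-style: per offset, the
Jensen-Shannon divergence (base-2 logs, bounded by 1 bit) between the two
strains' position weight matrices, with signed per-letter contributions
(probs_B - probs_A; positive means enriched in strain B, conventionally the
mutant, drawn below the axis).  Per-offset significance comes from a pooled
label-permutation test of context-set membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .rdna import BASE_ORDER, SPACER, RDNATemplate

DEFAULT_LOGO_WINDOW: tuple[int, ...] = tuple(range(-10, 6))


@dataclass
class PWM:
    """Position weight matrix over a context window.

    ``probs`` has shape (n_offsets, 4) in A,C,G,T order; each row sums to 1.
    """

    offsets: tuple[int, ...]
    probs: np.ndarray
    n_contexts: int

    def __post_init__(self) -> None:
        if self.probs.shape != (len(self.offsets), 4):
            raise ValueError("probs must be (n_offsets, 4)")
        if np.any(self.probs < 0) or np.any(np.abs(self.probs.sum(axis=1) - 1) > 1e-9):
            raise ValueError("each offset's probabilities must be >= 0 and sum to 1")


@dataclass
class DiffLogoResult:
    """Per-offset JS divergence, signed letter contributions, significance."""

    offsets: tuple[int, ...]
    jsd: np.ndarray
    letter_deltas: np.ndarray  # probs_b - probs_a, shape (n_offsets, 4)
    p_perm: np.ndarray | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray | None:
        return None if self.p_perm is None else self.p_perm < self.alpha

    def to_table(self) -> pd.DataFrame:
        data = {"offset": self.offsets, "jsd_bits": self.jsd}
        for k, base in enumerate(BASE_ORDER):
            data[f"delta_{base}"] = self.letter_deltas[:, k]
        if self.p_perm is not None:
            data["p_perm"] = self.p_perm
            data["significant"] = self.significant
        return pd.DataFrame(data)


def call_pause_sites(
    median_profile: np.ndarray,
    q: float,
    template: RDNATemplate,
    region_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Top-q% occupied positions within the named regions (default: spacers).

    Returns ``ceil(q/100 * n_region_positions)`` 0-based positions, sorted
    ascending; occupancy ties are broken in favor of the lower coordinate.
    """
    if not (0 < q <= 100):
        raise ValueError("q must be in (0, 100]")
    if region_names is None:
        pos = template.positions_of_class(SPACER)
    else:
        parts = [
            np.arange(r.start, r.end)
            for name in region_names
            for r in [template.region_by_name(name)]
        ]
        pos = np.concatenate(parts) if parts else np.empty(0, dtype=int)
    if pos.size == 0:
        raise ValueError("region restriction is empty")
    vals = np.asarray(median_profile, dtype=float)[pos]
    n_top = math.ceil(q / 100 * pos.size)
    order = np.lexsort((pos, -vals))  # highest value first; lower coordinate on ties
    return np.sort(pos[order[:n_top]])


def extract_contexts(
    template: RDNATemplate,
    positions: Sequence[int],
    window: Sequence[int] = DEFAULT_LOGO_WINDOW,
) -> tuple[list[str], int]:
    """Sequence contexts at ``position + offset`` for each window offset.

    Positions whose window leaves ``[0, length)`` are dropped and counted.
    Returns ``(contexts, n_dropped)``.
    """
    window = tuple(window)
    if 0 not in window:
        raise ValueError("window must include offset 0")
    lo, hi = min(window), max(window)
    seq = template.sequence
    contexts: list[str] = []
    dropped = 0
    for p in positions:
        if p + lo < 0 or p + hi >= template.length:
            dropped += 1
            continue
        contexts.append("".join(seq[p + o] for o in window))
    return contexts, dropped


def _encode_contexts(contexts: Sequence[str]) -> np.ndarray:
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate(BASE_ORDER):
        lut[ord(b)] = i
    mat = np.frombuffer("".join(contexts).encode("ascii"), dtype=np.uint8)
    coded = lut[mat].reshape(len(contexts), -1)
    if np.any(coded == 255):
        raise ValueError("contexts contain non-ACGT characters")
    return coded


def pwm_from_contexts(
    contexts: Sequence[str],
    pseudocount: float = 0.5,
    offsets: Sequence[int] | None = None,
) -> PWM:
    """Per-offset base frequencies, ``(count + pc) / (n + 4 pc)``."""
    if not contexts:
        raise ValueError("empty context list")
    lengths = {len(c) for c in contexts}
    if len(lengths) != 1:
        raise ValueError("contexts have unequal lengths")
    coded = _encode_contexts(contexts)
    n, width = coded.shape
    counts = np.stack([np.bincount(coded[:, j], minlength=4) for j in range(width)])
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    offs = tuple(offsets) if offsets is not None else tuple(range(width))
    return PWM(offsets=offs, probs=probs, n_contexts=n)


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=-1)


def js_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon divergence in bits: H(M) - (H(P)+H(Q))/2, M=(P+Q)/2.

    Symmetric and bounded in [0, 1] for base-2 logs; inputs must be
    distributions over the 4 bases (sum 1 within 1e-6).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for dist in (p, q):
        if dist.shape != (4,) or np.any(dist < 0) or abs(dist.sum() - 1) > 1e-6:
            raise ValueError("inputs must be length-4 distributions summing to 1")
    m = (p + q) / 2
    val = _entropy_bits(m) - (_entropy_bits(p) + _entropy_bits(q)) / 2
    return float(np.clip(val, 0.0, 1.0))


def _jsd_rows(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    m = (pa + pb) / 2
    return np.clip(_entropy_bits(m) - (_entropy_bits(pa) + _entropy_bits(pb)) / 2, 0.0, 1.0)


def diff_logo(pwm_a: PWM, pwm_b: PWM) -> DiffLogoResult:
    """Per-offset JSD between two PWMs plus signed letter contributions.

    ``letter_deltas = probs_b - probs_a``: positive values mark enrichment in
    strain B (the mutant by convention, rendered below the axis; the JSD itself
    stays non-negative — the sign convention lives entirely in the deltas).
    """
    if pwm_a.offsets != pwm_b.offsets:
        raise ValueError("PWMs have different windows")
    return DiffLogoResult(
        offsets=pwm_a.offsets,
        jsd=_jsd_rows(pwm_a.probs, pwm_b.probs),
        letter_deltas=pwm_b.probs - pwm_a.probs,
    )


def permutation_test(
    contexts_a: Sequence[str],
    contexts_b: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Pooled-label permutation p-values for the per-offset JSD.

    Context-set labels are permuted with set sizes preserved; per offset,
    ``p = (1 + #{permuted JSD >= observed}) / (n_perm + 1)``, so the minimum
    attainable p is ``1/(n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if not contexts_a or not contexts_b:
        raise ValueError("both context sets must be nonempty")
    coded = _encode_contexts(list(contexts_a) + list(contexts_b))
    na = len(contexts_a)
    n, width = coded.shape

    def _probs(rows: np.ndarray) -> np.ndarray:
        counts = np.stack([np.bincount(rows[:, j], minlength=4) for j in range(width)])
        return (counts + pseudocount) / (rows.shape[0] + 4 * pseudocount)

    observed = _jsd_rows(_probs(coded[:na]), _probs(coded[na:]))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(width, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pa = _probs(coded[perm[:na]])
        pb = _probs(coded[perm[na:]])
        exceed += _jsd_rows(pa, pb) >= observed
    return (1 + exceed) / (n_perm + 1)


def compare_pause_contexts(
    template: RDNATemplate,
    median_a: np.ndarray,
    median_b: np.ndarray,
    q: float = 2.5,
    window: Sequence[int] = DEFAULT_LOGO_WINDOW,
    region_names: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> DiffLogoResult:
    """End-to-end differential logo between two strains' median profiles.

    Calls top-q% pause sites per strain (spacer regions by default), extracts
    contexts, builds PWMs, and attaches permutation p-values.
    """
    window = tuple(window)
    sites_a = call_pause_sites(median_a, q, template, region_names)
    sites_b = call_pause_sites(median_b, q, template, region_names)
    ctx_a, _ = extract_contexts(template, sites_a, window)
    ctx_b, _ = extract_contexts(template, sites_b, window)
    pwm_a = pwm_from_contexts(ctx_a, pseudocount=pseudocount, offsets=window)
    pwm_b = pwm_from_contexts(ctx_b, pseudocount=pseudocount, offsets=window)
    result = diff_logo(pwm_a, pwm_b)
    result.p_perm = permutation_test(
        ctx_a, ctx_b, n_perm=n_perm, seed=seed, pseudocount=pseudocount
    )
    result.alpha = alpha
    return result


def write_contexts_fasta(contexts: Sequence[str], path: str, prefix: str = "ctx") -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(contexts):
            fh.write(f">{prefix}{i}\n{c}\n")


def write_pause_sites_bed(
    positions: Sequence[int], template: RDNATemplate, path: str
) -> None:
    """Pause sites as single-base BED intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for p in positions:
            fh.write(f"{template.name}\t{p}\t{p + 1}\tpause\n")
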