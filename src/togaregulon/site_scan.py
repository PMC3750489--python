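"""Additive PWM scoring and genome scanning.

A candidate site's score is the sum of the positional nucleotide weights of
its bases.  The detection threshold follows the comparative-genomics
convention: the lowest score observed among the training-set sites, so every
training site passes by construction and no statistical calibration of the
cutoff is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from togaregulon.genome_model import (
    GenomeAnnotation,
    Operon,
    UpstreamRegion,
    extract_upstream,
)
from togaregulon.motif_discovery import (
    COMPLEMENT_INDEX,
    MotifProfile,
    encode,
)

logger = logging.getLogger(__name__)


@dataclass
class ScanHit:
    """A scored window in an upstream region."""

    operon_id: str
    genome_id: str
    offset: int  # 0-based within the region, in region orientation
    strand: str  # relative to the region: "+" = as written
    sequence: str
    score: float
    profile_id: str = "motif"
    passed_threshold: bool = False


def score_site(profile: MotifProfile, seq: str) -> float:
    """Score one L-mer: the sum of per-position weights of its bases."""
    idx = encode(seq)
    if len(idx) != profile.width:
        raise ValueError(
            f"sequence length {len(idx)} != profile width {profile.width}"
        )
    w = profile.weights
    return float(w[idx, np.arange(profile.width)].sum())


def set_threshold(profile: MotifProfile, training_sites: list[str] | None = None) -> float:
    """Set the detection threshold to the minimum training-set score.

    ``training_sites`` defaults to the sequences of the profile's own
    training sites.  The threshold is stored on the profile and returned.
    """
    if training_sites is None:
        training_sites = [s.sequence for s in profile.training_sites]
    if not training_sites:
        raise ValueError("empty training set")
    profile.threshold = min(score_site(profile, s) for s in training_sites)
    return profile.threshold


def scan_region(
    profile: MotifProfile,
    region: UpstreamRegion,
    threshold: float | None = None,
    report_all: bool = False,
) -> list[ScanHit]:
    """Score every width-L window of a region on both strands.

    Hits with score >= threshold are returned sorted by (offset, strand).
    For palindromic profiles the +/- scores at an offset are equal by
    symmetry; such duplicate hits are collapsed to a single "+" hit.
    With ``report_all`` every window is returned regardless of threshold
    (``passed_threshold`` still reflects the cutoff).
    """
    if threshold is None:
        threshold = profile.threshold
    if np.isnan(threshold) and not report_all:
        raise ValueError("profile threshold unset; call set_threshold first")
    L = profile.width
    if len(region.sequence) < L:
        logger.warning("region %s shorter than L=%d; no hits", region.operon_id, L)
        return []
    seq = encode(region.sequence)
    n_win = len(seq) - L + 1
    idx = np.arange(L)
    windows = seq[np.arange(n_win)[:, None] + idx]
    w = profile.weights
    fwd = w[windows, idx].sum(axis=1)
    rc = COMPLEMENT_INDEX[windows][:, ::-1]
    rev = w[rc, idx].sum(axis=1)

    hits: list[ScanHit] = []
    for off in range(n_win):
        for strand, score, win in (("+", fwd[off], windows[off]), ("-", rev[off], rc[off])):
            if profile.palindromic and strand == "-" and np.isclose(score, fwd[off]):
                continue  # collapse the mirror hit
            passed = bool(score >= threshold)
            if passed or report_all:
                hits.append(
                    ScanHit(
                        operon_id=region.operon_id,
                        genome_id=region.genome_id,
                        offset=off,
                        strand=strand,
                        sequence="".join("ACGT"[b] for b in win),
                        score=float(score),
                        profile_id=profile.profile_id,
                        passed_threshold=passed,
                    )
                )
    return hits


def scan_genome(
    profile: MotifProfile,
    genome: GenomeAnnotation,
    operons: list[Operon],
    threshold: float | None = None,
    window: tuple[int, int] = (300, 20),
) -> dict[str, list[ScanHit]]:
    """Scan the upstream region of every operon; map operon_id -> hits.

    Operons whose upstream regions are unusable (too short after truncation)
    are reported with empty hit lists.
    """
    result: dict[str, list[ScanHit]] = {}
    for op in operons:
        region = extract_upstream(op, genome, window=window, operons=operons)
        if region is None:
            result[op.operon_id] = []
            continue
        result[op.operon_id] = scan_region(profile, region, threshold=threshold)
    return result


def hits_to_table(hits: list[ScanHit]):
    """Flatten hits into the TSV-ready table layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "operon_id": h.operon_id,
                "offset": h.offset,
                "strand": h.strand,
                "sequence": h.sequence,
                "score": round(h.score, 4),
                "passed": h.passed_threshold,
                "profile_id": h.profile_id,
            }
            for h in hits
        ],
        columns=[
            "genome_id",
            "operon_id",
            "offset",
            "strand",
            "sequence",
            "score",
            "passed",
            "profile_id",
        ],
    )
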