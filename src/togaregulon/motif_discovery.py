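"""De novo motif discovery and positional weight matrix construction.

The motif model is the classical one-occurrence-per-sequence (OOPS) model:
each upstream region in the training set carries (at most) one instance of a
width-L motif, and the rest of the sequence is i.i.d. background.  Discovery
is by Gibbs site sampling with a deterministic hill-climbing finish, restarted
from several random initialisations; the best alignment by total information
content wins.

Weights are log2 odds with a pseudocount:

    w(b, i) = log2[ (n(b,i) + p) / ((N + 4p) * q(b)) ]

with N aligned sites, pseudocount p (default 0.25 per base) and background
mononucleotide probabilities q.  A candidate site's score is the sum of the
weights of its bases, so any monotone transform of the per-column frequencies
preserves hit ranking; this particular form is fixed so thresholds are
reproducible.

Palindromic (homodimer) motifs are supported by symmetrising the count matrix
with its reverse-complement mirror and by scoring both strands during
discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int array; rejects ambiguity codes."""
    try:
        return np.array([BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from None


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


def reverse_complement(seq: str) -> str:
    return decode(COMPLEMENT_INDEX[encode(seq)][::-1])


@dataclass
class SiteInstance:
    """One candidate or training binding site within an upstream region."""

    operon_id: str
    genome_id: str
    offset: int
    strand_relative: str
    sequence: str
    score: float = float("nan")


@dataclass
class MotifProfile:
    """A positional weight matrix with its provenance.

    Attributes
    ----------
    counts : (4, L) array of site counts per base per position.
    background : length-4 probabilities for A, C, G, T.
    pseudocount : per-base pseudocount p added to counts.
    palindromic : whether the count matrix was symmetrised with its
        reverse-complement mirror.
    threshold : detection score cutoff (the minimum training-set score once
        :func:`togaregulon.site_scan.set_threshold` has run); NaN until set.
    """

    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.25
    palindromic: bool = False
    threshold: float = float("nan")
    profile_id: str = "motif"
    training_sites: list[SiteInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix")
        if not np.allclose(self.background.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")
        totals = self.counts.sum(axis=0)
        if not np.allclose(totals, totals[0]):
            raise ValueError("column count totals differ across positions")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sites(self) -> float:
        return float(self.counts[:, 0].sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudocounted per-column base frequencies (columns sum to 1)."""
        denom = self.n_sites + 4 * self.pseudocount
        return (self.counts + self.pseudocount) / denom

    @property
    def weights(self) -> np.ndarray:
        """Log2-odds weights w(b, i) against the background."""
        return np.log2(self.frequencies / self.background[:, None])

    def consensus(self) -> str:
        return decode(self.counts.argmax(axis=0))

    def reverse_complemented_counts(self) -> np.ndarray:
        return self.counts[COMPLEMENT_INDEX][:, ::-1]


def symmetrize_counts(counts: np.ndarray) -> np.ndarray:
    """Average a count matrix with its reverse-complement mirror."""
    counts = np.asarray(counts, dtype=float)
    return 0.5 * (counts + counts[COMPLEMENT_INDEX][:, ::-1])


def build_pwm(
    sites: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
    palindromic: bool = False,
    profile_id: str = "motif",
) -> MotifProfile:
    """Build a profile from aligned equal-length sites.

    Counts are raw occurrence counts; with ``palindromic`` they are averaged
    with the reverse-complement mirror, which makes the weight matrix satisfy
    w(b, i) = w(complement(b), L-1-i).
    """
    if not sites:
        raise ValueError("no sites given")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("sites have unequal lengths")
    counts = np.zeros((4, L))
    for s in sites:
        idx = encode(s)
        counts[idx, np.arange(L)] += 1
    if palindromic:
        counts = symmetrize_counts(counts)
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    return MotifProfile(
        counts=counts,
        background=bg,
        pseudocount=pseudocount,
        palindromic=palindromic,
        profile_id=profile_id,
    )


def information_content(profile: MotifProfile) -> tuple[np.ndarray, float]:
    """Per-position information content in bits, and its total.

    IC_i = 2 + sum_b f(b,i) log2 f(b,i), with f the pseudocounted
    frequencies; each column is in [0, 2] bits.
    """
    f = profile.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    per_column = 2.0 + terms.sum(axis=0)
    return per_column, float(per_column.sum())


# ---------------------------------------------------------------------------
# Gibbs site sampler (OOPS / ZOOPS)


def _alignment_counts(
    regions: list[np.ndarray], offsets: list[int], strands: list[int], L: int
) -> np.ndarray:
    counts = np.zeros((4, L))
    for seq, off, st in zip(regions, offsets, strands):
        if off < 0:
            continue
        window = seq[off : off + L]
        if st < 0:
            window = COMPLEMENT_INDEX[window][::-1]
        counts[window, np.arange(L)] += 1
    return counts


def _alignment_objective(
    counts: np.ndarray,
    pseudocount: float,
    palindromic: bool,
    bg: np.ndarray,
    zoops: bool = False,
    position_penalty: float = 0.0,
) -> float:
    """Total information content of the alignment's columns.

    In zero-or-one mode alignments may differ in size, so the objective is
    instead N times the profile-vs-background relative entropy minus the
    uniform site-position prior paid per included site — otherwise a tiny
    near-perfect alignment would dominate a full one.
    """
    if palindromic:
        counts = symmetrize_counts(counts)
    n = counts[:, 0].sum()
    f = (counts + pseudocount) / (n + 4 * pseudocount)
    if not zoops:
        per_column = 2.0 + np.where(f > 0, f * np.log2(f), 0.0).sum(axis=0)
        return float(per_column.sum())
    relent = float((f * np.log2(f / bg[:, None])).sum())
    return n * relent - position_penalty


def _window_scores(
    seq: np.ndarray, weights: np.ndarray, both_strands: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every L-window on + (and optionally -) strand.

    Returns (scores, strands) where scores[k] is the best-strand score of the
    window at offset k and strands[k] in {+1, -1}.
    """
    L = weights.shape[1]
    n_win = len(seq) - L + 1
    idx = np.arange(L)
    windows = seq[np.arange(n_win)[:, None] + idx]
    fwd = weights[windows, idx].sum(axis=1)
    if not both_strands:
        return fwd, np.ones(n_win, dtype=int)
    rc = COMPLEMENT_INDEX[windows][:, ::-1]
    rev = weights[rc, idx].sum(axis=1)
    strands = np.where(fwd >= rev, 1, -1)
    return np.maximum(fwd, rev), strands


def discover_profile(
    regions,
    L: int,
    symmetry: str = "none",
    n_restarts: int = 20,
    seed: int = 0,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    zoops: bool = False,
    n_iter: int = 200,
    profile_id: str = "motif",
) -> tuple[MotifProfile, list[SiteInstance]]:
    """Discover a shared width-L motif in a set of upstream regions.

    Parameters
    ----------
    regions : list of UpstreamRegion (or any objects with ``sequence``,
        ``operon_id`` and ``genome_id`` attributes).
    symmetry : "none" or "palindrome".  In palindrome mode both strands of
        every window are scored and the counts are symmetrised.
    n_restarts : independent Gibbs chains; the best final alignment by total
        information content is returned.  Each restart consumes its own
        seeded RNG stream, so increasing ``n_restarts`` never changes the
        earlier restarts and never decreases the best objective.
    zoops : if True, a region may contribute no site when its best window's
        log-odds score does not beat the uniform site-position prior
        (log2 of the number of scored windows on both strands) — the
        zero-or-one-occurrence-per-sequence decision rule.

    Returns the profile (with training sites attached) and the site list,
    one (or zero, under ``zoops``) per usable region.  Regions shorter than
    L are skipped with a warning; if all are too short, raises ValueError.
    """
    if symmetry not in ("none", "palindrome"):
        raise ValueError(f"unknown symmetry mode {symmetry!r}")
    palindromic = symmetry == "palindrome"
    usable = []
    for r in regions:
        if len(r.sequence) < L:
            logger.warning("region %s shorter than L=%d; skipped", r.operon_id, L)
            continue
        usable.append(r)
    if len(usable) < 2:
        raise ValueError("need at least 2 regions of length >= L")
    seqs = [encode(r.sequence) for r in usable]
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)

    best: tuple[float, list[int], list[int]] | None = None
    root = np.random.SeedSequence(seed)
    restart_seeds = root.spawn(n_restarts)
    for restart_idx in range(n_restarts):
        rng = np.random.default_rng(restart_seeds[restart_idx])
        offsets = [int(rng.integers(0, len(s) - L + 1)) for s in seqs]
        strands = [int(rng.choice([1, -1])) for _ in seqs]
        for sweep in range(n_iter):
            anneal = sweep >= n_iter // 2  # second half: deterministic climbing
            changed = False
            for i in range(len(seqs)):
                counts = _alignment_counts(
                    [s for j, s in enumerate(seqs) if j != i],
                    [o for j, o in enumerate(offsets) if j != i],
                    [st for j, st in enumerate(strands) if j != i],
                    L,
                )
                if palindromic:
                    counts = symmetrize_counts(counts)
                n_eff = counts[:, 0].sum()
                f = (counts + pseudocount) / (n_eff + 4 * pseudocount)
                weights = np.log2(f / bg[:, None])
                # both strands always: planted/real sites have no preferred
                # orientation relative to the downstream gene
                scores, win_strands = _window_scores(seqs[i], weights, True)
                if anneal:
                    k = int(scores.argmax())
                else:
                    p = np.exp2(scores - scores.max())
                    p /= p.sum()
                    k = int(rng.choice(len(p), p=p))
                new_strand = int(win_strands[k])
                # the zero-occurrence decision is only sound once the profile
                # has stabilised; during burn-in every region keeps a site
                if zoops and anneal and scores[k] <= np.log2(2.0 * len(scores)):
                    k = -1
                if (k, new_strand) != (offsets[i], strands[i]):
                    changed = True
                offsets[i], strands[i] = k, new_strand
            if anneal and not changed:
                break
        counts = _alignment_counts(seqs, offsets, strands, L)
        penalty = sum(
            np.log2(2.0 * (len(s) - L + 1))
            for s, o in zip(seqs, offsets)
            if o >= 0
        )
        obj = _alignment_objective(
            counts, pseudocount, palindromic, bg, zoops=zoops, position_penalty=penalty
        )
        if best is None or obj > best[0] + 1e-12:
            best = (obj, list(offsets), list(strands))
    assert best is not None
    _, offsets, strands = best

    if sum(1 for o in offsets if o >= 0) < 2:
        raise ValueError("zero-or-one mode retained fewer than 2 sites")
    site_seqs: list[str] = []
    sites: list[SiteInstance] = []
    for r, seq, off, st in zip(usable, seqs, offsets, strands):
        if off < 0:
            continue
        window = seq[off : off + L]
        if st < 0:
            window = COMPLEMENT_INDEX[window][::-1]
        s = decode(window)
        site_seqs.append(s)
        sites.append(
            SiteInstance(
                operon_id=r.operon_id,
                genome_id=r.genome_id,
                offset=off,
                strand_relative="+" if st > 0 else "-",
                sequence=s,
            )
        )
    profile = build_pwm(
        site_seqs,
        background=bg,
        pseudocount=pseudocount,
        palindromic=palindromic,
        profile_id=profile_id,
    )
    w = profile.weights
    for site in sites:
        site.score = float(w[encode(site.sequence), np.arange(L)].sum())
    profile.training_sites = sites
    return profile, sites


# ---------------------------------------------------------------------------
# Motif I/O and logos


def write_meme(profile: MotifProfile, path) -> None:
    """Write MEME minimal motif format (letter-probability matrix)."""
    f = profile.frequencies
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {q:.5f}" for b, q in zip(ALPHABET, profile.background))
            + "\n\n"
        )
        fh.write(f"MOTIF {profile.profile_id}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {profile.width} "
            f"nsites= {int(round(profile.n_sites))} E= 0\n"
        )
        for i in range(profile.width):
            fh.write(" ".join(f"{f[b, i]:.6f}" for b in range(4)) + "\n")


def read_meme(path) -> MotifProfile:
    """Read the first motif from a MEME minimal format file.

    Frequencies are converted back to effective counts via the stated nsites;
    thresholds are not stored in MEME files and stay unset.
    """
    background = UNIFORM_BACKGROUND.copy()
    rows: list[list[float]] = []
    nsites, motif_id, in_matrix = 1, "motif", False
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if line.startswith("Background letter frequencies"):
            vals = next(lines).split()
            background = np.array([float(vals[i]) for i in (1, 3, 5, 7)])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            in_matrix = True
            if "nsites=" in line:
                nsites = int(float(line.split("nsites=")[1].split()[0]))
        elif in_matrix:
            if not line.strip():
                break
            rows.append([float(x) for x in line.split()])
    freqs = np.array(rows).T  # 4 x L
    # Invert the pseudocount convention to recover effective counts; rounding
    # in the file can leave tiny negatives, so floor and renormalise columns.
    p = 0.25
    counts = np.clip(freqs * (nsites + 4 * p) - p, 0, None)
    counts *= nsites / counts.sum(axis=0, keepdims=True)
    return MotifProfile(
        counts=counts,
        background=background,
        pseudocount=p,
        profile_id=motif_id,
    )


def write_counts_tsv(profile: MotifProfile, path) -> None:
    """4 rows x L columns count matrix, header = 1-based positions."""
    import pandas as pd

    df = pd.DataFrame(
        profile.counts,
        index=list(ALPHABET),
        columns=[str(i + 1) for i in range(profile.width)],
    )
    df.to_csv(path, sep="\t", index_label="base")


def read_counts_tsv(path, **kwargs) -> MotifProfile:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col="base")
    counts = df.loc[list(ALPHABET)].to_numpy(dtype=float)
    return MotifProfile(counts=counts, **kwargs)


def render_logo(profile: MotifProfile, path, dpi: int = 150) -> None:
    """Render a stacked-letter sequence logo; letter height = f(b,i) * IC_i.

    Letters are drawn as scaled glyph outlines with matplotlib, tallest on
    top, in the standard base colours.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    ic, _ = information_content(profile)
    f = profile.frequencies
    fig, ax = plt.subplots(figsize=(max(2, profile.width * 0.4), 2.2))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    for i in range(profile.width):
        heights = sorted(
            ((f[b, i] * ic[i], ALPHABET[b]) for b in range(4)), key=lambda t: t[0]
        )
        y = 0.0
        for h, letter in heights:
            if h <= 1e-3:
                continue
            tp = TextPath((0, 0), letter, size=1.0, prop=fp)
            bbox = tp.get_extents()
            sx = 0.9 / bbox.width
            sy = h / bbox.height
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(sx, sy)
                .translate(i + 0.05, y)
            )
            ax.add_patch(PathPatch(tp, transform=transform + ax.transData,
                                   facecolor=colors[letter], edgecolor="none"))
            y += h
    ax.set_xlim(0, profile.width)
    ax.set_ylim(0, 2)
    ax.set_xticks([i + 0.5 for i in range(profile.width)])
    ax.set_xticklabels([str(i + 1) for i in range(profile.width)], fontsize=7)
    ax.set_ylabel("bits")
    for spine in ("top", "right"):
        ax.spines[spine].set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
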