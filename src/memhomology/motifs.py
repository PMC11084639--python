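"""Ungapped motif discovery (one-occurrence-per-sequence EM), exact PWM
scanning statistics, and signature-region recovery rates.

The discovery step fits a position weight matrix by expectation-
maximisation under the OOPS assumption — every sequence contains exactly
one motif occurrence, at an unknown position with a uniform prior.  The
scanning step scores every window of every sequence against the PWM and
converts the best score to a p-value under an *exact* background null
computed by position-wise convolution of the discretised log-odds scores,
then to an E-value against the scanned set.  A family's recovery rate is
the percentage of its members with at least one significant hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .composition import BACKGROUND_VECTOR
from .core_io import AA20, Topology, ValidationError, spawn_rng

logger = logging.getLogger("memhomology")

MIN_WIDTH, MAX_WIDTH = 8, 50
EM_PSEUDOCOUNT_TOTAL = 0.1
EM_TOL = 1e-6
EM_MAX_ITER = 200
SCORE_RESOLUTION = 0.01  # bits per bin of the exact null

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position residue probabilities with their background model."""

    probs: np.ndarray       # (width, 20), rows sum to 1
    background: np.ndarray  # (20,)
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 20:
            raise ValidationError("PWM must be (width, 20)")
        if not (MIN_WIDTH <= probs.shape[0] <= MAX_WIDTH):
            raise ValidationError(
                f"motif width must lie in [{MIN_WIDTH}, {MAX_WIDTH}], got {probs.shape[0]}"
            )
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 20) log2(p/bg) scores."""
        return np.log2(self.probs / self.background)

    @property
    def information_content(self) -> float:
        """Total relative entropy vs background, in bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * np.log2(self.probs / self.background)
        return float(np.nansum(terms))

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.probs.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        idx = [rng.choice(20, p=row) for row in self.probs]
        return "".join(AA20[i] for i in idx)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# PWM width={self.width} alphabet={AA20}\n")
            for row in self.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_text(cls, path) -> "PositionWeightMatrix":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                rows.append([float(x) for x in line.split()])
        return cls(np.array(rows), BACKGROUND_VECTOR.copy())


def pwm_from_consensus(consensus: str, identity: float = 0.8,
                       background: np.ndarray | None = None) -> PositionWeightMatrix:
    """A PWM putting ``identity`` mass on each consensus letter and the rest
    on the background (renormalised over the other 19 letters)."""
    bg = BACKGROUND_VECTOR if background is None else background
    probs = np.zeros((len(consensus), 20))
    for t, c in enumerate(consensus):
        i = _AA_INDEX[c]
        others = bg.copy()
        others[i] = 0.0
        others /= others.sum()
        probs[t] = (1.0 - identity) * others
        probs[t, i] = identity
    return PositionWeightMatrix(probs, bg.copy())


@dataclass(frozen=True)
class MotifHit:
    """Best PWM hit in one sequence."""

    seq_id: str
    start: int
    score_bits: float
    p_value: float
    evalue: float


@dataclass(frozen=True)
class MotifSite:
    """EM site assignment: the posterior-modal start in one sequence."""

    seq_id: str
    start: int
    posterior: float


# ---------------------------------------------------------------------------
# Discovery (OOPS EM)
# ---------------------------------------------------------------------------

def _encode(seqs) -> list[np.ndarray]:
    out = []
    for s in seqs:
        res = s.residues if hasattr(s, "residues") else s
        out.append(np.array([_AA_INDEX.get(c, -1) for c in res], dtype=np.int64))
    return out


def _window_log_odds(encoded: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """Log-odds of every window; 'X' (code -1) scores 0 at its position."""
    w = log_ratio.shape[0]
    windows = sliding_window_view(encoded, w)  # (npos, w)
    scores = log_ratio[np.arange(w), windows.clip(min=0)]
    scores = np.where(windows >= 0, scores, 0.0)
    return scores.sum(axis=1)


def discover_motif_oops(seqs, width: int, n_starts: int = 5, seed: int = 0
                        ) -> tuple[PositionWeightMatrix, list[MotifSite]]:
    """EM motif discovery with exactly one site per sequence.

    E-step: posterior over start positions per sequence (uniform prior,
    window likelihood ratio vs background).  M-step: PWM re-estimated from
    posterior-weighted counts with background pseudocounts (total weight
    0.1).  Iterates to a log-likelihood change below 1e-6 or 200 rounds;
    the best of ``n_starts`` restarts (each initialised from an observed
    window) is returned with the final modal sites.
    """
    if not (MIN_WIDTH <= width <= MAX_WIDTH):
        raise ValidationError(f"motif width must lie in [{MIN_WIDTH}, {MAX_WIDTH}]")
    seqs = list(seqs)
    if n_starts < 1:
        raise ValidationError("need at least one EM start")
    ids = [getattr(s, "id", f"seq{i}") for i, s in enumerate(seqs)]
    encoded = _encode(seqs)
    for sid, e in zip(ids, encoded):
        if len(e) < width:
            raise ValidationError(f"{sid}: sequence shorter than motif width {width}")
    bg = BACKGROUND_VECTOR
    log_bg = np.log(bg)
    # Precompute windows once: per sequence, (npos, width) residue codes,
    # their validity mask ('X' = -1) and flat (position-in-motif, code) bins.
    windows_list = [sliding_window_view(e, width) for e in encoded]
    valid_list = [w >= 0 for w in windows_list]
    flat_bins = [
        (np.arange(width)[None, :] * 20 + w.clip(min=0)).ravel()
        for w in windows_list
    ]

    def em_run(init_probs: np.ndarray):
        # The M-step uses background pseudocounts, so the EM-monotone
        # objective is the MAP objective: log-likelihood plus the matching
        # Dirichlet log-prior term.
        probs = init_probs
        prev_obj = -np.inf
        history = []
        for _ in range(EM_MAX_ITER):
            log_ratio = np.log(probs) - log_bg  # natural log for the E-step
            counts = np.zeros(width * 20)
            ll = 0.0
            posts = []
            for windows, valid, bins in zip(windows_list, valid_list, flat_bins):
                scores = log_ratio[np.arange(width)[None, :], windows.clip(min=0)]
                lo = np.where(valid, scores, 0.0).sum(axis=1)
                lse = float(logsumexp(lo))
                ll += lse - np.log(len(lo))
                post = np.exp(lo - lse)
                posts.append(post)
                weights = (np.repeat(post, width) * valid.ravel())
                counts += np.bincount(bins, weights=weights, minlength=width * 20)
            prior = float(EM_PSEUDOCOUNT_TOTAL * (bg * np.log(probs)).sum())
            objective = ll + prior
            probs = counts.reshape(width, 20) + EM_PSEUDOCOUNT_TOTAL * bg
            probs /= probs.sum(axis=1, keepdims=True)
            history.append((objective, ll))
            if objective - prev_obj < EM_TOL and np.isfinite(prev_obj):
                break
            prev_obj = objective
        return probs, ll, posts, history

    def pwm_from_sites(starts: list[int]) -> np.ndarray:
        counts = np.zeros((width, 20))
        for e, s in zip(encoded, starts):
            window = e[s:s + width]
            for t, a in enumerate(window):
                if a >= 0:
                    counts[t, a] += 1.0
        probs = counts + EM_PSEUDOCOUNT_TOTAL * bg
        return probs / probs.sum(axis=1, keepdims=True)

    def oops_likelihood(probs) -> float:
        """One E-step pass: the OOPS log-likelihood of a fixed PWM."""
        log_ratio = np.log(probs) - log_bg
        ll = 0.0
        for windows, valid, _ in zip(windows_list, valid_list, flat_bins):
            scores = log_ratio[np.arange(width)[None, :], windows.clip(min=0)]
            lo = np.where(valid, scores, 0.0).sum(axis=1)
            ll += float(logsumexp(lo)) - np.log(len(lo))
        return ll

    def refine_shift(probs, ll, posts):
        """Move the whole site set left/right if that raises the objective.

        EM can converge with every site displaced by the same few residues
        (the window then straddles the true motif); re-seeding from a
        uniformly shifted site set escapes this family of local optima.
        Candidate shifts are screened with a single-pass likelihood and only
        the best one is refined by full EM.
        """
        for _ in range(4):
            starts = [int(p.argmax()) for p in posts]
            candidates = []
            for delta in range(-width // 2, width // 2 + 1):
                if delta == 0:
                    continue
                shifted = [
                    min(max(s + delta, 0), len(e) - width)
                    for s, e in zip(starts, encoded)
                ]
                cand = pwm_from_sites(shifted)
                candidates.append((oops_likelihood(cand), cand))
            screen_ll, screen_probs = max(candidates, key=lambda c: c[0])
            if screen_ll <= ll + EM_TOL:
                break
            cand_probs, cand_ll, cand_posts, _ = em_run(screen_probs)
            if cand_ll <= ll + EM_TOL:
                break
            probs, ll, posts = cand_probs, cand_ll, cand_posts
        return probs, ll, posts

    best = None
    for start_idx in range(n_starts):
        rng = spawn_rng(seed, "oops-init", start_idx)
        si = int(rng.integers(len(encoded)))
        pos = int(rng.integers(len(encoded[si]) - width + 1))
        window = encoded[si][pos:pos + width]
        init = np.tile(bg, (width, 1)) * 0.4
        for t, a in enumerate(window):
            if a >= 0:
                init[t, a] += 0.6
        init /= init.sum(axis=1, keepdims=True)
        probs, ll, posts, history = em_run(init)
        objectives = [obj for obj, _ in history]
        if any(b - a < -1e-8 for a, b in zip(objectives, objectives[1:])):
            raise AssertionError("EM objective decreased")  # EM guarantee
        probs, ll, posts = refine_shift(probs, ll, posts)
        if best is None or ll > best[1]:
            best = (probs, ll, posts)

    probs, ll, posts = best
    pwm = PositionWeightMatrix(probs, bg.copy(), log_likelihood=ll)
    sites = [
        MotifSite(sid, int(post.argmax()), float(post.max()))
        for sid, post in zip(ids, posts)
    ]
    return pwm, sites


# ---------------------------------------------------------------------------
# Exact scanning statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the per-window log-odds score.

    Computed by position-wise convolution of scores discretised to
    ``resolution`` bits; the tail function is conservative at bin edges.
    """

    probs: np.ndarray     # probability per bin
    offset: int           # score of bin 0, in resolution units
    resolution: float
    _tail: np.ndarray = None  # reverse cumulative, filled in post-init

    def __post_init__(self) -> None:
        tail = np.cumsum(self.probs[::-1])[::-1]
        object.__setattr__(self, "_tail", tail)

    def sf(self, score_bits: float) -> float:
        """P(window score >= score_bits) under the background model."""
        b = int(np.floor(score_bits / self.resolution + 1e-9)) - self.offset
        if b < 0:
            return 1.0
        if b >= len(self.probs):
            return 0.0
        return float(self._tail[b])


def pwm_score_distribution(pwm: PositionWeightMatrix,
                           resolution: float = SCORE_RESOLUTION) -> ScoreDistribution:
    """Exact distribution of the PWM log-odds score of a background window."""
    lo = np.round(pwm.log_odds / resolution).astype(np.int64)  # (w, 20)
    bg = pwm.background
    dist = np.array([1.0])
    offset = 0
    for t in range(pwm.width):
        smin, smax = int(lo[t].min()), int(lo[t].max())
        new = np.zeros(len(dist) + (smax - smin))
        for a in range(20):
            s = int(lo[t, a]) - smin
            new[s:s + len(dist)] += bg[a] * dist
        dist = new
        offset += smin
    total = dist.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"null distribution mass {total} != 1")
    return ScoreDistribution(dist, offset, resolution)


def scan_sequences(pwm: PositionWeightMatrix, seqs, evalue_threshold: float = 1e-4,
                   distribution: ScoreDistribution | None = None) -> list[MotifHit]:
    """Best-hit-per-sequence PWM scan with exact p-values.

    The best window score in a sequence of L residues has
    p_seq = 1 - (1 - p_window)^(L - w + 1) under the background null;
    E = p_seq * number of scanned sequences.  Hits with E at or below the
    threshold are returned (at most one per sequence).
    """
    dist = distribution or pwm_score_distribution(pwm)
    log_ratio = pwm.log_odds * np.log(2.0)  # natural-log units for scoring
    seqs = list(seqs)
    n_scanned = len(seqs)
    hits: list[MotifHit] = []
    for i, s in enumerate(seqs):
        sid = getattr(s, "id", f"seq{i}")
        res = s.residues if hasattr(s, "residues") else s
        if len(res) < pwm.width:
            logger.warning("%s: shorter than motif width, skipped", sid)
            continue
        enc = np.array([_AA_INDEX.get(c, -1) for c in res], dtype=np.int64)
        scores_nat = _window_log_odds(enc, log_ratio)
        best_pos = int(scores_nat.argmax())
        best_bits = float(scores_nat[best_pos] / np.log(2.0))
        p_window = dist.sf(best_bits)
        n_windows = len(scores_nat)
        p_seq = -np.expm1(n_windows * np.log1p(-min(p_window, 1.0 - 1e-16)))
        evalue = p_seq * n_scanned
        if evalue <= evalue_threshold:
            hits.append(MotifHit(sid, best_pos, best_bits, float(p_seq), float(evalue)))
    return hits


def recovery_rate(hits, family_members) -> float:
    """Percentage of family members with at least one hit."""
    members = list(family_members)
    if not members:
        raise ValidationError("empty family")
    hit_ids = {h.seq_id for h in hits}
    return 100.0 * sum(1 for m in members if m in hit_ids) / len(members)


def locate_motif(hits, topologies: dict[str, Topology], width: int) -> dict[str, int]:
    """Histogram of the membrane segment containing each hit's midpoint.

    Keys are 'TMS 1', 'RL 2', ... (1-based ordinal among membrane segments)
    or 'loop' when the midpoint falls outside any membrane segment.
    """
    histogram: dict[str, int] = {}
    for hit in hits:
        topo = topologies.get(hit.seq_id)
        if topo is None:
            continue
        mid = hit.start + width // 2
        label = "loop"
        for ordinal, seg in enumerate(topo.membrane_segments(), 1):
            if seg.start <= mid < seg.end:
                label = f"{seg.kind} {ordinal}"
                break
        histogram[label] = histogram.get(label, 0) + 1
    return histogram
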