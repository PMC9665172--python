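"""Synthetic corpus generator with the statistical structure the pipeline assumes.

The generator runs the piecewise multilevel growth model *forward*: a
person-day emotion value is the fixed-effect trajectory for the user's
group (built from the slope design and the gamma coefficients), plus the
user's correlated random effects applied to the same design row, plus
residual noise.  Default parameter values are the study regime: the
published fixed-effect and random-SD estimates, group sizes of 1,236
locked-down and 12,714 comparison users, a 29-day window around the
2020-01-23 lockdown, and a residual SD derived from the published
between-person variance and intraclass correlation.  Posting intensity
defaults to ~0.14 active days per user-day, matching the published
corpus totals (57,685 posts by 13,950 users over 29 days).

Post *text* is rendered from a synthetic lexicon so that re-scoring the
text through the real pipeline reproduces each post's target valence and
arousal within a declared tolerance.  Words are built from disjoint
character pools (an initial-character pool and a continuation pool, with
a third pool reserved for non-lexicon filler) and kept prefix-free, so
forward maximum matching recovers the construction token multiset
exactly and the generator's token bookkeeping is exact.  Targets outside
the lexicon's achievable score hull are projected onto it and the
projected value is recorded as the rendering target.  Noise wrapping
(repost chains, hashtags, mentions, URLs, filler) exercises every
cleaning path; geotags are drawn inside each group's region box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Point, Polygon
from shapely.ops import nearest_points

from .aggregate import DEFAULT_REGIONS, BoundingBox, RegionConfig, StudyWindow, DEFAULT_WINDOW
from .lexicon import Lexicon, LexiconEntry
from .mlm import DEFAULT_ANCHORS, build_slope_design

# Published empty-model variance components: between-person variance and
# ICC per outcome, from which the residual SD is derived.
EMPTY_BETWEEN_VAR = {"valence": 0.332, "arousal": 0.252}
EMPTY_ICC = {"valence": 0.134, "arousal": 0.098}

# Published fixed effects (immediate-response model / longer-term model).
TABLE2_GAMMAS = {
    "valence": {
        "intercept": 0.337, "slope1": 0.123, "slope2": 0.118, "slope3": -0.146,
        "slope4": 0.000, "location": -0.037,
        "slope2:location": -0.172, "slope3:location": 0.109,
    },
    "arousal": {
        "intercept": 2.365, "slope1": 0.089, "slope2": 0.293, "slope3": -0.315,
        "slope4": 0.000, "location": -0.042,
        "slope2:location": -0.262, "slope3:location": 0.218,
    },
}
TABLE3_GAMMAS = {
    "valence": {
        "intercept": 0.339, "slope1": 0.124, "slope2": 0.094, "slope3": -0.128,
        "slope4": 0.000, "location": -0.080, "slope4:location": -0.004,
    },
    "arousal": {
        "intercept": 2.378, "slope1": 0.085, "slope2": 0.261, "slope3": -0.284,
        "slope4": 0.001, "location": -0.109, "slope4:location": 0.003,
    },
}
TABLE2_RANDOM_SD = {
    "valence": {"intercept": 0.452, "slope2": 0.259, "slope3": 0.260},
    "arousal": {"intercept": 0.265, "slope2": 0.569, "slope3": 0.607},
}
TABLE3_RANDOM_SD = {
    "valence": {"intercept": 0.356, "slope4": 0.021},
    "arousal": {"intercept": 0.257, "slope4": 0.016},
}

# Character pools for synthetic words: initial characters, continuation
# characters, and filler characters, pairwise disjoint CJK ranges.
_INITIAL_POOL = [chr(c) for c in range(0x4E00, 0x4E00 + 800)]
_CONT_POOL = [chr(c) for c in range(0x5400, 0x5400 + 800)]
_FILLER_POOL = [chr(c) for c in range(0x7000, 0x7000 + 400)]

# Sampling box for comparison-group geotags (well outside the Hubei box).
NON_HUBEI_BOX = BoundingBox(39.0, 41.0, 115.6, 117.5)


def residual_sd_from_icc(between_var: float, icc: float) -> float:
    """Residual SD implied by a between-person variance and an ICC.

    Inverts icc = s2_b / (s2_b + s2_e) for the within-person variance.
    """
    if not 0 < icc < 1:
        raise ValueError(f"ICC must be in (0, 1), got {icc}")
    return math.sqrt(between_var * (1.0 - icc) / icc)


def default_gammas(model: str, outcome: str) -> dict:
    if model == "model2":
        return dict(TABLE3_GAMMAS[outcome])
    return dict(TABLE2_GAMMAS[outcome])


def default_random_sd(model: str, outcome: str) -> dict:
    if model == "empty":
        return {"intercept": math.sqrt(EMPTY_BETWEEN_VAR[outcome])}
    if model == "model2":
        return dict(TABLE3_RANDOM_SD[outcome])
    return dict(TABLE2_RANDOM_SD[outcome])


@dataclass(frozen=True)
class SynthConfig:
    """Full generative parameterization.

    The defaults reproduce the study regime; any field can be overridden
    (typically the group sizes, for desk-scale runs).  ``model`` selects
    which random-effect structure drives the generator: "model1"
    (random intercept + event-day slopes), "model2" (random intercept +
    longer-term slope) or "empty" (random intercept only).  ``gammas``
    and ``random_sd`` default to the published estimates for the chosen
    model; ``random_corr`` is the common correlation among a user's
    random effects (0 by default — the published tables print no
    correlations).
    """

    seed: int = 20200123
    n_wuhan: int = 1236
    n_non_hubei: int = 12714
    window: StudyWindow = DEFAULT_WINDOW
    anchors: tuple = DEFAULT_ANCHORS
    model: str = "model1"
    gammas: Optional[dict] = None          # {outcome: {term: value}}
    random_sd: Optional[dict] = None       # {outcome: {term: sd}}
    random_corr: float = 0.0
    residual_sd: Optional[dict] = None     # {outcome: sd}
    p_post_day: float = 0.14               # chance a user is active on a day
    extra_posts_mean: float = 0.1          # posts per active day = 1 + Poisson
    dataset2: bool = True                  # force >=1 pre- and post-event day
    within_day_sd: float = 0.0             # per-post target noise around the person-day value
    # lexicon shape
    lexicon_size: int = 7088
    word_length_range: tuple = (2, 3)
    arousal_curve: tuple = (2.156, 0.368)  # arousal = c0 + c2 * valence^2 + noise
    arousal_noise_sd: float = 1.2
    # text rendering
    n_words_range: tuple = (3, 12)
    score_tolerance: float = 0.05
    hull_margin: float = 0.15              # projection depth inside the score hull
    p_repost: float = 0.3
    p_repost_fallback: float = 0.2         # given a repost: own comment left empty
    p_hashtag: float = 0.15
    p_mention: float = 0.2
    p_url: float = 0.15
    p_filler: float = 0.5
    p_geotag: float = 0.9
    regions: RegionConfig = field(default_factory=lambda: DEFAULT_REGIONS)
    non_hubei_box: BoundingBox = field(default_factory=lambda: NON_HUBEI_BOX)

    def resolved_gammas(self, outcome: str) -> dict:
        if self.gammas and outcome in self.gammas:
            return dict(self.gammas[outcome])
        return default_gammas(self.model, outcome)

    def resolved_random_sd(self, outcome: str) -> dict:
        if self.random_sd and outcome in self.random_sd:
            return dict(self.random_sd[outcome])
        return default_random_sd(self.model, outcome)

    def resolved_residual_sd(self, outcome: str) -> float:
        if self.residual_sd and outcome in self.residual_sd:
            return float(self.residual_sd[outcome])
        return residual_sd_from_icc(EMPTY_BETWEEN_VAR[outcome], EMPTY_ICC[outcome])

    def random_cov(self, outcome: str) -> tuple[list, np.ndarray]:
        """(random term names, covariance matrix) for one outcome."""
        sds = self.resolved_random_sd(outcome)
        terms = list(sds)
        s = np.array([sds[t] for t in terms], dtype=float)
        q = len(terms)
        corr = np.full((q, q), self.random_corr, dtype=float)
        np.fill_diagonal(corr, 1.0)
        cov = corr * np.outer(s, s)
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-12:
            raise ValueError("random-effect covariance is not positive semi-definite")
        return terms, cov


@dataclass
class SynthTruth:
    """Ground truth sufficient to recompute every downstream quantity."""

    config: SynthConfig
    users: pd.DataFrame                    # user_id, group, location, U_* columns
    person_days: pd.DataFrame              # latent values (+ render targets after rendering)
    posts: Optional[pd.DataFrame] = None   # per-post targets, achieved scores, token multisets


def gen_lexicon(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> Lexicon:
    """Generate a synthetic valence-arousal lexicon.

    Valence is uniform on [-4, 4]; arousal follows the V-shaped
    valence-arousal relation (a convex quadratic in valence) plus noise,
    clipped to [0, 8].  Words are unique, prefix-free, and use character
    pools disjoint from the filler pool, so dictionary matching on
    rendered text is exact.
    """
    if config.lexicon_size < 10:
        raise ValueError("lexicon_size must be at least 10")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.word_length_range
    if not (2 <= lo <= hi):
        raise ValueError(f"word lengths must be >= 2, got {config.word_length_range}")
    words: list[str] = []
    seen: set[str] = set()
    prefixes: set[str] = set()
    while len(words) < config.lexicon_size:
        length = int(rng.integers(lo, hi + 1))
        head = _INITIAL_POOL[rng.integers(0, len(_INITIAL_POOL))]
        tail = "".join(
            _CONT_POOL[i] for i in rng.integers(0, len(_CONT_POOL), size=length - 1)
        )
        word = head + tail
        if word in seen or word[:2] in seen or (length == 2 and word in prefixes):
            continue
        seen.add(word)
        if length > 2:
            prefixes.add(word[:2])
        words.append(word)
    c0, c2 = config.arousal_curve
    valence = rng.uniform(-4.0, 4.0, size=len(words))
    arousal = c0 + c2 * valence**2 + rng.normal(0.0, config.arousal_noise_sd, len(words))
    arousal = np.clip(arousal, 0.0, 8.0)
    return Lexicon(
        LexiconEntry(w, float(v), float(a)) for w, v, a in zip(words, valence, arousal)
    )


def _fixed_curve(config: SynthConfig, outcome: str, design: pd.DataFrame,
                 location: int) -> np.ndarray:
    gam = config.resolved_gammas(outcome)
    total = np.zeros(len(design))
    for term, value in gam.items():
        if term == "intercept":
            x = np.ones(len(design))
        elif term == "location":
            x = np.full(len(design), float(location))
        elif ":" in term:
            slope, _ = term.split(":")
            x = design[slope].to_numpy(float) * float(location)
        else:
            x = design[term].to_numpy(float)
        total += value * x
    return total


def _random_design(design: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(design)))
        else:
            cols.append(design[t].to_numpy(float))
    return np.column_stack(cols)


def gen_person_days(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, SynthTruth]:
    """Simulate person-day emotion values for both groups.

    Returns the person-day table (user_id, group, location, date,
    valence, arousal) and the SynthTruth carrying each user's random
    effects.  Activity is Bernoulli per user-day; under the
    longitudinal-cohort emulation every user is guaranteed at least one
    active day before the event and one on/after it.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    design = build_slope_design(config.window, config.anchors)
    dates = design.index.to_list()
    n_days = len(dates)
    event_idx = dates.index(config.window.event)

    outcomes = ("valence", "arousal")
    curves = {
        (o, loc): _fixed_curve(config, o, design, loc)
        for o in outcomes for loc in (0, 1)
    }
    re_terms = {o: config.random_cov(o)[0] for o in outcomes}
    re_cov = {o: config.random_cov(o)[1] for o in outcomes}
    Z = {o: _random_design(design, re_terms[o]) for o in outcomes}
    res_sd = {o: config.resolved_residual_sd(o) for o in outcomes}

    n_total = config.n_wuhan + config.n_non_hubei
    user_ids = [f"u{i:06d}" for i in range(n_total)]
    locations = np.concatenate(
        [np.ones(config.n_wuhan, dtype=int), np.zeros(config.n_non_hubei, dtype=int)]
    )
    user_rows, pd_rows = [], []
    for i, (uid, loc) in enumerate(zip(user_ids, locations)):
        active = rng.random(n_days) < config.p_post_day
        if config.dataset2:
            if not active[:event_idx].any():
                active[rng.integers(0, event_idx)] = True
            if not active[event_idx:].any():
                active[rng.integers(event_idx, n_days)] = True
        elif not active.any():
            active[rng.integers(0, n_days)] = True
        idx = np.flatnonzero(active)
        values = {}
        urow = {"user_id": uid, "group": "wuhan" if loc else "non_hubei",
                "location": int(loc)}
        for o in outcomes:
            U = rng.multivariate_normal(np.zeros(len(re_terms[o])), re_cov[o],
                                        method="cholesky")
            e = rng.normal(0.0, res_sd[o], size=len(idx))
            values[o] = curves[(o, int(loc))][idx] + Z[o][idx] @ U + e
            for t, u in zip(re_terms[o], U):
                urow[f"U_{o}_{t}"] = float(u)
        user_rows.append(urow)
        for k, j in enumerate(idx):
            pd_rows.append(
                {
                    "user_id": uid,
                    "group": urow["group"],
                    "location": int(loc),
                    "date": dates[j],
                    "valence": float(values["valence"][k]),
                    "arousal": float(values["arousal"][k]),
                }
            )
    users = pd.DataFrame(user_rows)
    person_days = pd.DataFrame(pd_rows)
    truth = SynthTruth(config=config, users=users, person_days=person_days.copy())
    return person_days, truth


class _ScoreHull:
    """Renderable (valence, arousal) region of a lexicon.

    Combines the convex hull of the lexicon's score points (eroded by a
    margin) with a local-density criterion: a target is only reliably
    expressible as a short post's weighted mean where the lexicon has
    several words nearby.  ``project`` moves a point inside the hull;
    ``toward_dense`` steps a stubborn target toward the nearest
    well-covered word.
    """

    def __init__(self, lexicon: Lexicon, margin: float,
                 density_k: int = 12, density_radius: float = 0.35):
        pts = lexicon.to_frame()[["valence", "arousal"]].to_numpy(float)
        hull = ConvexHull(pts)
        poly = Polygon(pts[hull.vertices])
        shrunk = poly.buffer(-margin)
        self.poly = shrunk if not shrunk.is_empty else poly
        tree = cKDTree(pts)
        kth = tree.query(pts, k=density_k + 1)[0][:, -1]
        dense = pts[kth <= density_radius]
        self._dense_tree = cKDTree(dense if len(dense) else pts)

    def project(self, v: float, a: float) -> tuple[float, float, bool]:
        p = Point(v, a)
        if self.poly.covers(p):
            return v, a, False
        q = nearest_points(self.poly, p)[0]
        return float(q.x), float(q.y), True

    def toward_dense(self, v: float, a: float, step: float = 0.35
                     ) -> tuple[float, float]:
        """Move a fraction of the way toward the nearest dense word."""
        _, i = self._dense_tree.query([v, a])
        qv, qa = self._dense_tree.data[i]
        return v + step * (qv - v), a + step * (qa - a)


def _swap_refine(
    idx: np.ndarray,
    sv: float,
    sa: float,
    target_v: float,
    target_a: float,
    V: np.ndarray,
    A: np.ndarray,
    tol: float,
    max_passes: int = 10,
) -> tuple[np.ndarray, float]:
    """Best-improvement single-token swap passes on a candidate set."""
    idx = idx.copy()
    k = len(idx)
    err = math.hypot(sv / k - target_v, sa / k - target_a)
    for _ in range(max_passes):
        if err <= tol:
            break
        improved = False
        for j in range(k):
            base_v = sv - V[idx[j]]
            base_a = sa - A[idx[j]]
            d = ((base_v + V) / k - target_v) ** 2 + ((base_a + A) / k - target_a) ** 2
            best = int(np.argmin(d))
            new_err = math.sqrt(d[best])
            if new_err < err - 1e-12:
                sv = base_v + V[best]
                sa = base_a + A[best]
                idx[j] = best
                err = new_err
                improved = True
        if not improved:
            break
    return idx, err


def _greedy_tokens(
    target_v: float,
    target_a: float,
    V: np.ndarray,
    A: np.ndarray,
    k: int,
    first: Optional[int] = None,
    tol: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Greedy pick of k indices steering the mean toward the target,
    refined by best-improvement single-token swap passes."""
    idx = np.empty(k, dtype=int)
    sv = sa = 0.0
    for j in range(k):
        if j == 0 and first is not None:
            idx[0] = first
        else:
            need_v = (k * target_v - sv) / (k - j)
            need_a = (k * target_a - sa) / (k - j)
            d = (V - need_v) ** 2 + (A - need_a) ** 2
            idx[j] = int(np.argmin(d))
        sv += V[idx[j]]
        sa += A[idx[j]]
    return _swap_refine(idx, sv, sa, target_v, target_a, V, A, tol)


def _extend_tokens(
    idx: np.ndarray,
    target_v: float,
    target_a: float,
    V: np.ndarray,
    A: np.ndarray,
    khi: int,
    tol: float,
) -> tuple[np.ndarray, float]:
    """Grow a token set one word at a time toward the target mean,
    re-running swap refinement after each extension."""
    idx = list(idx)
    sv = sum(float(V[i]) for i in idx)
    sa = sum(float(A[i]) for i in idx)
    k = len(idx)
    err = math.hypot(sv / k - target_v, sa / k - target_a)
    while err > tol and k < khi:
        k += 1
        # the word that would move the enlarged mean exactly onto target
        d = (V - (k * target_v - sv)) ** 2 + (A - (k * target_a - sa)) ** 2
        j = int(np.argmin(d))
        idx.append(j)
        sv += V[j]
        sa += A[j]
        err = math.hypot(sv / k - target_v, sa / k - target_a)
        if err > tol:
            refined, refined_err = _swap_refine(
                np.array(idx), sv, sa, target_v, target_a, V, A, tol
            )
            if refined_err < err:
                idx = list(refined)
                sv = sum(float(V[i]) for i in idx)
                sa = sum(float(A[i]) for i in idx)
                err = refined_err
    return np.array(idx), err


def _pick_tokens(
    target_v: float,
    target_a: float,
    V: np.ndarray,
    A: np.ndarray,
    k: int,
    tol: float,
    rng: Optional[np.random.Generator] = None,
    khi: Optional[int] = None,
    n_restarts: int = 8,
) -> np.ndarray:
    """Choose k (up to khi) lexicon indices whose mean score approximates
    the target.

    The greedy/swap construction can stall in a local minimum where the
    lexicon is sparse; restarts seeded with a random near-target first
    token, plus one-word extensions of the best candidate, escape most
    of them.
    """
    khi = k if khi is None else max(k, khi)
    idx, err = _greedy_tokens(target_v, target_a, V, A, k, tol=tol)
    if err <= tol or rng is None:
        return idx
    d = (V - target_v) ** 2 + (A - target_a) ** 2
    near = np.argsort(d)[:30]
    for _ in range(n_restarts):
        first = int(near[rng.integers(0, len(near))])
        cand, cand_err = _greedy_tokens(target_v, target_a, V, A, k,
                                        first=first, tol=tol)
        if cand_err < err:
            idx, err = cand, cand_err
        if err <= tol:
            return idx
    # still stuck: extend the best candidate toward the maximum length
    ext, ext_err = _extend_tokens(idx, target_v, target_a, V, A, khi, tol)
    if ext_err < err:
        idx = ext
    return idx


def _sample_box(box: BoundingBox, rng: np.random.Generator) -> tuple[float, float]:
    return (
        float(rng.uniform(box.lat_min, box.lat_max)),
        float(rng.uniform(box.lon_min, box.lon_max)),
    )


def render_posts(
    person_days: pd.DataFrame,
    lexicon: Lexicon,
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Render raw post records whose scores reproduce the person-day values.

    For each person-day, a small number of posts is emitted; each post's
    word multiset is chosen so that its weighted-average valence and
    arousal land within ``score_tolerance`` of the post's target (the
    person-day value projected onto the lexicon's achievable hull).
    Posts are then wrapped in platform noise — repost chains (with
    prior-comment decoys drawn from the lexicon, which cleaning must
    discard), hashtag markers, mentions, URLs, and non-lexicon filler —
    and stamped with timestamps and group-consistent geotags.

    Returns (raw_posts, post_truth); post_truth records per-post targets,
    achieved scores, token multisets, and whether the tolerance had to be
    relaxed (infeasible target after swap refinement).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    frame = lexicon.to_frame()
    words = frame["word"].to_numpy()
    V = frame["valence"].to_numpy(float)
    A = frame["arousal"].to_numpy(float)
    hull = _ScoreHull(lexicon, margin=max(config.hull_margin, config.score_tolerance))
    klo, khi = config.n_words_range

    def _feasible_target(v: float, a: float
                         ) -> tuple[float, float, bool, Optional[np.ndarray]]:
        """Project into the hull, then verify the target is actually
        expressible at the maximum post length; step stubborn targets
        toward dense lexicon territory until it is.  Returns the
        verified token set so posts can fall back on it."""
        tv, ta, moved = hull.project(v, a)
        for _ in range(6):
            idx = _pick_tokens(tv, ta, V, A, khi, config.score_tolerance, rng)
            err = math.hypot(V[idx].mean() - tv, A[idx].mean() - ta)
            if err <= config.score_tolerance:
                return tv, ta, moved, idx
            tv, ta = hull.toward_dense(tv, ta)
            moved = True
        return tv, ta, moved, None

    post_rows, truth_rows = [], []
    targets_v, targets_a, projected_flags = [], [], []
    for rec in person_days.itertuples(index=False):
        tv, ta, projected, idx_ok = _feasible_target(
            float(rec.valence), float(rec.arousal)
        )
        targets_v.append(tv)
        targets_a.append(ta)
        projected_flags.append(projected)
        n_posts = 1 + rng.poisson(config.extra_posts_mean)
        for _ in range(n_posts):
            ptv, pta = tv, ta
            fallback_idx = idx_ok
            if config.within_day_sd > 0:
                ptv, pta, _, fallback_idx = _feasible_target(
                    tv + rng.normal(0, config.within_day_sd),
                    ta + rng.normal(0, config.within_day_sd),
                )
            k = int(rng.integers(klo, khi + 1))
            idx = _pick_tokens(ptv, pta, V, A, k, config.score_tolerance, rng,
                               khi=khi)
            err = math.hypot(V[idx].mean() - ptv, A[idx].mean() - pta)
            if err > config.score_tolerance and fallback_idx is not None:
                idx = fallback_idx
                err = math.hypot(V[idx].mean() - ptv, A[idx].mean() - pta)
            k = len(idx)
            achieved_v = float(V[idx].mean())
            achieved_a = float(A[idx].mean())
            relaxed = err > config.score_tolerance
            tokens = [words[i] for i in idx]
            rng.shuffle(tokens)
            counts: dict[str, int] = {}
            for t in tokens:
                counts[t] = counts.get(t, 0) + 1

            parts = list(tokens)
            if rng.random() < config.p_hashtag and parts:
                j = int(rng.integers(0, len(parts)))
                parts[j] = f"#{parts[j]}#"
            if rng.random() < config.p_filler:
                fill = "".join(
                    _FILLER_POOL[i]
                    for i in rng.integers(0, len(_FILLER_POOL), size=rng.integers(2, 7))
                )
                # filler goes between tokens, never inside one
                slot = int(rng.integers(0, len(parts) + 1))
                parts.insert(slot, fill)
            content = "".join(parts)
            if rng.random() < config.p_mention:
                content = f"@user{rng.integers(0, 10**6)} " + content
            if rng.random() < config.p_url:
                content += f" http://t.cn/{rng.integers(0, 10**8):x}"

            is_repost = rng.random() < config.p_repost
            fallback = False
            if is_repost:
                handle = f"u{rng.integers(0, 10**6)}"
                if rng.random() < config.p_repost_fallback:
                    text = f"//@{handle}:{content}"
                    fallback = True
                else:
                    decoy = "".join(
                        words[i] for i in rng.integers(0, len(words),
                                                       size=rng.integers(1, 4))
                    )
                    text = f"{content} //@{handle}:{decoy}"
            else:
                text = content

            lat = lon = None
            if rng.random() < config.p_geotag:
                box = (config.regions.wuhan if rec.location == 1
                       else config.non_hubei_box)
                lat, lon = _sample_box(box, rng)
            seconds = int(rng.integers(0, 86400))
            ts = (f"{rec.date.isoformat()}T{seconds // 3600:02d}:"
                  f"{(seconds % 3600) // 60:02d}:{seconds % 60:02d}+08:00")
            pid = f"p{len(post_rows):07d}"
            post_rows.append(
                {
                    "post_id": pid,
                    "user_id": rec.user_id,
                    "timestamp": ts,
                    "text": text,
                    "is_repost": is_repost,
                    "lat": lat,
                    "lon": lon,
                    "region_label": None,
                }
            )
            truth_rows.append(
                {
                    "post_id": pid,
                    "user_id": rec.user_id,
                    "date": rec.date,
                    "target_valence": ptv,
                    "target_arousal": pta,
                    "achieved_valence": achieved_v,
                    "achieved_arousal": achieved_a,
                    "n_tokens": k,
                    "relaxed": relaxed,
                    "fallback_path": fallback,
                    "token_counts": counts,
                }
            )
    posts = pd.DataFrame(post_rows)
    truth = pd.DataFrame(truth_rows)
    person_days = person_days.assign(
        render_target_valence=targets_v,
        render_target_arousal=targets_a,
        target_projected=projected_flags,
    )
    return posts, truth, person_days


@dataclass
class SynthCorpus:
    """A fully rendered synthetic corpus plus its ground truth."""

    lexicon: Lexicon
    posts: pd.DataFrame
    truth: SynthTruth


def gen_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate lexicon, person-day trajectories, and rendered posts."""
    rng = np.random.default_rng(config.seed)
    lexicon = gen_lexicon(config, rng)
    person_days, truth = gen_person_days(config, rng)
    posts, post_truth, person_days = render_posts(person_days, lexicon, config, rng)
    truth.person_days = person_days
    truth.posts = post_truth
    return SynthCorpus(lexicon=lexicon, posts=posts, truth=truth)
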