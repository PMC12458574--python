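"""Bayes-optimal observer for the rule-shifting task.

The observer maintains a posterior P_t(f_k) over the N unique features
displayed at a level, each feature being the hypothesis "f_k is the
rewarded feature". Feedback is deterministic given the rule, so the
likelihood of reward r_t under hypothesis f_k is

    P(r_t | f_k) = 1/n_c   if r_t = 1 and f_k is on the chosen stimulus,
                   0       if r_t = 0 and f_k is on the chosen stimulus,
                   1/n_u   if r_t = 0 and f_k is on an unchosen stimulus,
                   0       if r_t = 1 and f_k is on an unchosen stimulus,

with n_c the number of unique features on the chosen stimulus and n_u the
number pooled across all unchosen stimuli. When feedback invalidates every
currently supported hypothesis (the Bayes normaliser is zero), the
posterior is reset to uniform: the observer knows covert rule shifts occur
and re-evaluates from a neutral standpoint.

Two certainty summaries on the participants' 0-100 confidence scale:

* General Certainty  GC = 100 * (log2 N - S) / log2 N, the proportion of
  maximal entropy eliminated, where S = -sum P log2 P.
* Choice Certainty   CC = 100 * sum of P over the chosen stimulus's
  features: the probability the chosen stimulus carries the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import StimulusDisplay, TrialRecord

__all__ = [
    "BeliefState",
    "init_beliefs",
    "outcome_likelihood",
    "likelihood_vector",
    "update_beliefs",
    "posterior_entropy",
    "general_certainty",
    "choice_certainty",
    "run_observer",
]

#: probabilities below this are treated as exactly zero before the
#: zero-normaliser (reset) test, so resets are robust to float residue
PROB_FLOOR = 1e-15
_RESET_TOL = 1e-12


@dataclass(frozen=True)
class BeliefState:
    """Posterior over the N unique displayed features."""

    features: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if len(self.features) != p.size:
            raise ValueError("features/probs length mismatch")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("probs must be a distribution (sum 1, nonnegative)")

    @property
    def n(self) -> int:
        return len(self.features)

    def prob_of(self, feature: str) -> float:
        return float(self.probs[self.features.index(feature)])


def init_beliefs(features) -> BeliefState:
    """Uniform prior P_0(f_k) = 1/N over the level's unique features."""
    features = tuple(features)
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature labels")
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    n = len(features)
    return BeliefState(features, np.full(n, 1.0 / n))


def _chosen_unchosen(display: StimulusDisplay, choice: int):
    chosen = set(display.features_of(choice))
    unchosen = set()
    for i in range(display.n_stimuli):
        if i != choice:
            unchosen.update(display.stimuli[i])
    return chosen, unchosen


def outcome_likelihood(feature: str, outcome: int, display: StimulusDisplay,
                       choice: int) -> float:
    """P(r_t | f_k) for a single feature hypothesis."""
    chosen, unchosen = _chosen_unchosen(display, choice)
    if feature not in chosen and feature not in unchosen:
        raise ValueError(f"feature {feature!r} not on display")
    if outcome == 1:
        return 1.0 / len(chosen) if feature in chosen else 0.0
    return 1.0 / len(unchosen) if feature in unchosen else 0.0


def likelihood_vector(belief_features, display: StimulusDisplay, choice: int,
                      outcome: int) -> np.ndarray:
    """Eq.-style likelihood for every feature in ``belief_features`` at once."""
    chosen, unchosen = _chosen_unchosen(display, choice)
    lik = np.empty(len(belief_features))
    for k, f in enumerate(belief_features):
        if f in chosen:
            lik[k] = 1.0 / len(chosen) if outcome == 1 else 0.0
        elif f in unchosen:
            lik[k] = 1.0 / len(unchosen) if outcome == 0 else 0.0
        else:
            raise ValueError(f"feature {f!r} not on display")
    return lik


def update_beliefs(belief: BeliefState, display: StimulusDisplay, choice: int,
                   outcome: int) -> tuple[BeliefState, bool]:
    """Bayes update of the feature posterior; reset to uniform if invalidated.

    Returns ``(posterior, reset)``. The reset fires when the normalising
    denominator vanishes, i.e. observed feedback contradicts every
    hypothesis currently carrying probability mass.
    """
    shown = set(display.all_features)
    if shown != set(belief.features):
        raise ValueError("display feature set does not match belief features")
    lik = likelihood_vector(belief.features, display, choice, outcome)
    prior = np.where(belief.probs < PROB_FLOOR, 0.0, belief.probs)
    unnorm = lik * prior
    z = unnorm.sum()
    if z < _RESET_TOL:
        n = belief.n
        return BeliefState(belief.features, np.full(n, 1.0 / n)), True
    return BeliefState(belief.features, unnorm / z), False


def posterior_entropy(belief: BeliefState) -> float:
    """Shannon entropy -sum P log2 P in bits, with 0*log2(0) := 0."""
    p = belief.probs[belief.probs > 0]
    return float(-(p * np.log2(p)).sum())


def _snap_endpoints(gc: float) -> float:
    # uniform/point-mass entropies carry last-ulp residue for N not a
    # power of two; the scale endpoints are exact by definition
    if abs(gc) < 1e-9:
        return 0.0
    if abs(gc - 100.0) < 1e-9:
        return 100.0
    return float(gc)


def general_certainty(belief: BeliefState, literal: bool = False) -> float:
    """Entropy-based certainty on the 0-100 confidence scale.

    Default: 100 * (log2 N - S) / log2 N, i.e. the proportion of maximal
    uncertainty eliminated (0 at uniform, 100 at a point mass). With
    ``literal=True`` the variant 100 * (log2 N - log2 S) / log2 N is
    computed instead (undefined at S=0); it is exposed only for
    sensitivity analysis.
    """
    n = belief.n
    if n < 2:
        raise ValueError("general certainty undefined for N < 2")
    s = posterior_entropy(belief)
    if literal:
        return 100.0 * (np.log2(n) - np.log2(s)) / np.log2(n)
    return _snap_endpoints(100.0 - 100.0 * s / np.log2(n))


def choice_certainty(belief: BeliefState, display: StimulusDisplay,
                     choice: int) -> float:
    """100 x posterior probability that the chosen stimulus holds the target."""
    feats = display.features_of(choice)
    idx = [belief.features.index(f) for f in feats]
    return float(100.0 * belief.probs[idx].sum())


def run_observer(trials: list[TrialRecord], literal_gc: bool = False) -> pd.DataFrame:
    """Replay a participant's trial log through the ideal observer.

    Beliefs are re-initialised to uniform at the start of every level.
    Two trace timings are emitted per trial:

    * ``gc_pre`` / ``cc_pre`` - from the belief updated through trial t-1
      plus the trial-t choice. This is the quantity aligned with the
      participant's confidence report, which precedes feedback, and is
      the default regressor downstream.
    * ``gc_post`` / ``cc_post`` - after incorporating trial-t feedback
      (the timing plotted in shift-locked illustrations).

    ``entropy_bits`` is the posterior entropy; ``reset`` flags trials whose
    feedback invalidated all supported hypotheses.
    """
    rows = []
    current_level = None
    prev_index = None
    probs = None
    features: tuple[str, ...] = ()
    feat_index: dict[str, int] = {}
    log2n = 1.0

    def _entropy(p: np.ndarray) -> float:
        pos = p[p > 0]
        return float(-(pos * np.log2(pos)).sum())

    def _gc(p: np.ndarray) -> float:
        if literal_gc:
            return 100.0 * (log2n - np.log2(_entropy(p))) / log2n
        return _snap_endpoints(100.0 - 100.0 * _entropy(p) / log2n)

    for rec in trials:
        if rec.level_id != current_level:
            current_level = rec.level_id
            features = rec.display.all_features
            if len(set(features)) != len(features):
                raise ValueError("duplicate feature labels on display")
            feat_index = {f: k for k, f in enumerate(features)}
            log2n = float(np.log2(len(features)))
            probs = np.full(len(features), 1.0 / len(features))
            prev_index = rec.trial_index - 1
        if rec.trial_index != prev_index + 1:
            raise ValueError(
                f"non-contiguous trial indices within level {rec.level_id}: "
                f"{prev_index} -> {rec.trial_index}"
            )
        prev_index = rec.trial_index

        chosen_idx = np.fromiter(
            (feat_index[f] for f in rec.display.features_of(rec.choice)),
            dtype=np.intp,
        )
        gc_pre = _gc(probs)
        cc_pre = float(100.0 * probs[chosen_idx].sum())

        n_feat = len(features)
        chosen_mask = np.zeros(n_feat, dtype=bool)
        chosen_mask[chosen_idx] = True
        n_c = int(chosen_mask.sum())
        n_u = n_feat - n_c
        if rec.outcome == 1:
            lik = np.where(chosen_mask, 1.0 / n_c, 0.0)
        else:
            lik = np.where(chosen_mask, 0.0, 1.0 / n_u)
        prior = np.where(probs < PROB_FLOOR, 0.0, probs)
        unnorm = lik * prior
        z = unnorm.sum()
        if z < _RESET_TOL:
            probs = np.full(n_feat, 1.0 / n_feat)
            reset = True
        else:
            probs = unnorm / z
            reset = False

        rows.append(
            (rec.participant_id, rec.level_id, rec.trial_index,
             gc_pre, cc_pre, _gc(probs), float(100.0 * probs[chosen_idx].sum()),
             _entropy(probs), reset)
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "level", "trial", "gc_pre", "cc_pre",
                 "gc_post", "cc_post", "entropy_bits", "reset"],
    )
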