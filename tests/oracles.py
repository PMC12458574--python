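"""Independent brute-force oracles used by the observer tests.

These recompute posteriors from scratch with set logic and literal
likelihood products, never via the package's incremental update path.
"""

import numpy as np


def step_likelihood(feature, display, choice, outcome):
    """Literal per-feature feedback likelihood via set membership."""
    chosen = set(display.stimuli[choice])
    others = set()
    for i, s in enumerate(display.stimuli):
        if i != choice:
            others.update(s)
    if outcome == 1:
        return 1.0 / len(chosen) if feature in chosen else 0.0
    return 1.0 / len(others) if feature in others else 0.0


def brute_force_trace(features, steps):
    """Posterior after each step, recomputed as a full product each time.

    ``steps`` is a list of (display, choice, outcome). Returns a list of
    (posterior_vector, support_set, reset_flag). After a contradiction
    (all products zero) the posterior is uniform and history restarts.
    """
    feats = list(features)
    n = len(feats)
    start = 0
    out = []
    for t in range(len(steps)):
        prod = np.full(n, 1.0 / n)
        for display, choice, outcome in steps[start:t + 1]:
            prod = prod * np.array(
                [step_likelihood(f, display, choice, outcome) for f in feats]
            )
        if prod.sum() == 0.0:
            start = t + 1
            post = np.full(n, 1.0 / n)
            out.append((post, set(feats), True))
        else:
            post = prod / prod.sum()
            out.append((post, {f for f, p in zip(feats, post) if p > 0}, False))
    return out


def consistent_set_trace(features, steps):
    """Hypotheses consistent with all feedback since the last reset."""
    all_feats = set(features)
    current = set(all_feats)
    out = []
    for display, choice, outcome in steps:
        chosen = set(display.stimuli[choice])
        candidate = current & chosen if outcome == 1 else current - chosen
        if not candidate:
            current = set(all_feats)
            out.append((set(all_feats), True))
        else:
            current = candidate
            out.append((set(current), False))
    return out
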