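"""Covariate-stratified sequential group assignment.

Animals arrive one at a time with a post-stroke severity score and must be
assigned to a treatment arm so that arm-mean scores stay comparable — the
stratified step-by-step randomization used when a full cohort is not
available up front (minimization in the clinical-trials sense, with the
post-stroke neurological score as the single balancing covariate).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def stratified_assign(post_stroke_scores: Sequence[float], n_arms: int,
                      seed: int | np.random.Generator = 0) -> list[int]:
    """Assign each animal, in arrival order, to the arm that best balances
    mean scores.

    For each candidate arm the objective is evaluated as if the animal were
    assigned there:

    1. range (max - min) of arm sizes after assignment;
    2. tie-break: range of the mean score over non-empty arms;
    3. final tie-break: seeded uniform choice.

    Size balance leads the key because the mean-spread term alone is
    degenerate early on: as long as only one arm holds animals its spread
    is zero, so a spread-first greedy would stack every arrival into the
    same arm. With sizes held within one of each other, each "round" over
    the arms places the arrival where the arm means stay closest.

    Deterministic given ``seed``. Returns one arm index (0..n_arms-1) per
    animal; arm sizes never differ by more than one.
    """
    scores = [float(s) for s in post_stroke_scores]
    if not scores:
        raise ValueError("need at least one score")
    if n_arms < 2:
        raise ValueError("need at least two arms")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    sums = np.zeros(n_arms)
    counts = np.zeros(n_arms, dtype=int)
    labels: list[int] = []
    for s in scores:
        best_key = None
        best_arms: list[int] = []
        for a in range(n_arms):
            sums[a] += s
            counts[a] += 1
            means = sums[counts > 0] / counts[counts > 0]
            mean_range = float(means.max() - means.min())
            size_range = int(counts.max() - counts.min())
            sums[a] -= s
            counts[a] -= 1
            key = (size_range, round(mean_range, 12))
            if best_key is None or key < best_key:
                best_key, best_arms = key, [a]
            elif key == best_key:
                best_arms.append(a)
        choice = best_arms[rng.integers(len(best_arms))]
        sums[choice] += s
        counts[choice] += 1
        labels.append(choice)
    return labels
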