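"""t-SNE embedding of arrays with multi-restart objective selection.

The embedding is recomputed from many random initializations and the restart
with the lowest final KL divergence (the t-SNE objective) is kept — random
restarts are the standard guard against the method's non-convex landscape.
The exact (non-approximated) gradient is used throughout: at a few dozen
arrays it is cheaper than tree approximation and removes the approximation
hyperparameter.  Restart seeds are fixed at 1..n_restarts so the selection
is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.manifold import TSNE

__all__ = ["Embedding", "default_perplexity", "tsne_embed"]


@dataclass(frozen=True)
class Embedding:
    """Selected 2-d embedding: coordinates, its KL objective, the seed and
    restart index that produced it, and the objectives of every restart."""

    coordinates: pd.DataFrame  # index = array_id, columns = ["x", "y"]
    objective: float
    seed: int
    restart_index: int
    all_objectives: tuple[float, ...]


def default_perplexity(n_items: int) -> float:
    """min(30, floor((n-1)/3)): the usual default, capped by the feasibility
    bound perplexity < (n-1)/3."""
    return float(min(30, (n_items - 1) // 3))


def tsne_embed(profiles: pd.DataFrame, perplexity: float | None = None,
               n_restarts: int = 100, iters: int = 1000,
               learning_rate: float = 200.0) -> Embedding:
    """Embed the rows of an (items x features) frame in 2-d.

    Runs exact t-SNE ``n_restarts`` times with random initialization
    (seeds 1..n_restarts), records each final KL divergence, and returns the
    restart with the minimum objective.
    """
    n = len(profiles)
    if n < 4:
        raise ValueError("t-SNE needs at least 4 items")
    if perplexity is None:
        perplexity = default_perplexity(n)
    if not 0 < perplexity < (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n} (need < (n-1)/3)"
        )
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    mat = profiles.to_numpy(float)
    best = None
    objectives = []
    for restart, seed in enumerate(range(1, n_restarts + 1)):
        model = TSNE(
            n_components=2,
            perplexity=perplexity,
            early_exaggeration=12.0,
            learning_rate=learning_rate,
            max_iter=iters,
            init="random",
            random_state=seed,
            method="exact",
        )
        coords = model.fit_transform(mat)
        kl = float(model.kl_divergence_)
        objectives.append(kl)
        if best is None or kl < best[0]:
            best = (kl, coords, seed, restart)
    kl, coords, seed, restart = best
    return Embedding(
        coordinates=pd.DataFrame(coords, index=profiles.index, columns=["x", "y"]),
        objective=kl,
        seed=seed,
        restart_index=restart,
        all_objectives=tuple(objectives),
    )
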