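"""Activity-weighted Jensen-Shannon dissimilarity between actor processes.

The dissimilarity between actors i and j is the weighted average of the
weekly Jensen-Shannon distances between their theme distributions,

    d_ij = sum_t w_ij(t) * JS(P_i(t) || P_j(t)),
    w_ij(t) = C_i(t) * C_j(t) / sum_tau C_i(tau) * C_j(tau),

so weeks where both actors are highly active dominate, and weeks where
either is inactive contribute nothing.  With base-2 logarithms the JS
distance — the square root of the Jensen-Shannon divergence — lies in
[0, 1], hence so does d_ij.  The weighted average is NOT itself a metric:
the weights differ per pair, and the triangle inequality can fail (the test
suite carries a constructed counterexample).

Pairs of actors with no co-active week have no defined d_ij; they are
recorded and assigned the configured fallback (maximal dissimilarity by
default) or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from traceclust.errors import ConfigurationError, NoCoactiveWeeksError
from traceclust.themes import ThemeProcess


def js_distance(
    p, q, base: float = 2.0, sqrt: bool = True, tol: float = 1e-6
) -> float:
    """Jensen-Shannon distance between two probability vectors.

    Returns sqrt(JSD(p, q)) with logarithms in ``base`` (default 2, so the
    value lies in [0, 1]); ``sqrt=False`` returns the divergence itself.
    0*log(0) is treated as 0, so zero entries are fine without smoothing.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ConfigurationError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < -tol):
            raise ConfigurationError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > tol:
            raise ConfigurationError(f"{name} does not sum to 1 (got {v.sum()})")
    d = float(jensenshannon(p, q, base=base))
    if np.isnan(d):  # identical vectors can produce 0/0 inside scipy
        d = 0.0
    return d if sqrt else d * d


def pair_weights(C_i: np.ndarray, C_j: np.ndarray) -> np.ndarray:
    """Weekly weights w_ij(t) = C_i(t)C_j(t) / sum_tau C_i(tau)C_j(tau).

    Raises :class:`NoCoactiveWeeksError` when no week has both counts
    positive (zero denominator).
    """
    C_i = np.asarray(C_i, dtype=float)
    C_j = np.asarray(C_j, dtype=float)
    if C_i.shape != C_j.shape:
        raise ConfigurationError("count vectors must have the same length")
    if np.any(C_i < 0) or np.any(C_j < 0):
        raise ConfigurationError("event counts must be non-negative")
    prod = C_i * C_j
    denom = prod.sum()
    if denom <= 0:
        raise NoCoactiveWeeksError("the two actors share no co-active week")
    return prod / denom


@dataclass
class DissimilarityMatrix:
    """Symmetric matrix of pairwise dissimilarities with actor labels."""

    actor_ids: list[str]
    D: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.D, index=self.actor_ids, columns=self.actor_ids).to_csv(
            path, index_label="actor_id"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(actor_ids=list(df.columns), D=df.to_numpy(dtype=float))

    def to_phylip(self, path: str | Path) -> None:
        """Lower-triangle text format for generic clustering tools."""
        lines = [str(len(self.actor_ids))]
        for i, a in enumerate(self.actor_ids):
            row = " ".join(f"{self.D[i, j]:.10f}" for j in range(i))
            lines.append(f"{a} {row}".rstrip())
        Path(path).write_text("\n".join(lines) + "\n")


def pairwise_dissimilarity(
    processes: list[ThemeProcess],
    log_base: float = 2.0,
    sqrt: bool = True,
    missing_pair: str = "max",
) -> DissimilarityMatrix:
    """All-pairs activity-weighted JS dissimilarity matrix.

    ``missing_pair='max'`` assigns d=1.0 to pairs with no co-active week
    (they share no observed behavior) and records them; ``'drop'``
    iteratively removes the actors involved in the most undefined pairs
    until none remain.
    """
    if len(processes) < 2:
        raise ConfigurationError("need at least two processes")
    if missing_pair not in ("max", "drop"):
        raise ConfigurationError(f"unknown missing_pair policy {missing_pair!r}")
    window = processes[0].weeks
    for proc in processes:
        if proc.weeks != window:
            raise ConfigurationError("processes are on different week windows")

    n = len(processes)
    ids = [p.actor_id for p in processes]
    C = np.stack([p.C for p in processes]).astype(float)  # (n, T)
    P = np.stack([p.P for p in processes])  # (n, T, M)

    D = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            prod = C[i] * C[j]
            denom = prod.sum()
            if denom <= 0:
                undefined.append((ids[i], ids[j]))
                D[i, j] = D[j, i] = 1.0
                continue
            w = prod / denom
            active = prod > 0
            d = 0.0
            for t in np.nonzero(active)[0]:
                d += w[t] * js_distance(
                    P[i, t], P[j, t], base=log_base, sqrt=sqrt
                )
            D[i, j] = D[j, i] = d

    if missing_pair == "drop" and undefined:
        from collections import Counter

        counts = Counter()
        bad = set(undefined)
        for a, b in undefined:
            counts[a] += 1
            counts[b] += 1
        removed: set[str] = set()
        while bad:
            worst = max(counts, key=lambda a: (counts[a], a))
            removed.add(worst)
            bad = {pr for pr in bad if worst not in pr}
            counts = Counter()
            for a, b in bad:
                counts[a] += 1
                counts[b] += 1
        keep = [i for i, a in enumerate(ids) if a not in removed]
        return DissimilarityMatrix(
            actor_ids=[ids[i] for i in keep],
            D=D[np.ix_(keep, keep)],
            undefined_pairs=undefined,
        )
    return DissimilarityMatrix(actor_ids=ids, D=D, undefined_pairs=undefined)
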