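"""Finite-context models (FCMs) and substitution-tolerant Markov models (STMMs).

An order-k FCM estimates P(symbol | previous k symbols) from context->symbol
counts with additive smoothing.  An STMM reads the same count table but keeps
its own, possibly *edited*, context history: when the observed symbol differs
from the model's best prediction and a substitution budget (over a sliding
window) permits, the prediction is recorded instead of the observation, so an
isolated mismatch does not destroy an otherwise deep matching context.

Count tables are trained once on the reference and frozen: probability
queries never modify them (relative-compression contract — only information
learned from the reference can reduce the target's code length).

Contexts are packed 2 bits/symbol into a 64-bit signed integer key, exactly
(no lossy fingerprinting), which caps the order at 31 (62 bits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "MAX_ORDER",
    "FCMConfig",
    "STMMConfig",
    "FCMCounts",
    "STMMState",
    "train_fcm",
    "fcm_probability",
    "context_distribution",
    "stmm_next",
    "ModelConfig",
]

MAX_ORDER = 31  # 2 bits/symbol in a non-negative signed 64-bit key


@dataclass(frozen=True)
class FCMConfig:
    """Configuration of one finite-context model.

    order: context depth k (0..32).
    alpha: additive-smoothing pseudo-count (> 0); default 1/16 — a low alpha
        sharpens high-order models on DNA.
    use_inverted_repeats: also count the reverse-complement of every training
        event (off by default).
    """

    order: int
    alpha: float = 1.0 / 16.0
    use_inverted_repeats: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.order <= MAX_ORDER:
            raise ValueError(f"order must be in [0, {MAX_ORDER}], got {self.order}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class STMMConfig:
    """Configuration of one substitution-tolerant Markov model.

    The model reads the count table of the FCM at index ``share_counts_with``
    in the mixture's model list (the two must have equal order) and applies
    at most ``max_substitutions`` history edits per sliding ``window``.
    """

    order: int
    alpha: float = 1.0 / 16.0
    max_substitutions: int = 8
    window: int = 64
    share_counts_with: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.order <= MAX_ORDER:
            raise ValueError(f"order must be in [0, {MAX_ORDER}], got {self.order}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.max_substitutions < 0:
            raise ValueError("max_substitutions must be >= 0")
        if self.window < max(1, self.max_substitutions):
            raise ValueError("window must be >= max_substitutions and >= 1")


ModelConfig = Union[FCMConfig, STMMConfig]


class FCMCounts:
    """Context -> 4 event counts, trained by counting and then frozen.

    ``table`` maps a packed context key to a length-4 count list; it is never
    modified by probability queries.
    """

    __slots__ = ("order", "table", "total_events", "_packed")

    def __init__(self, order: int):
        self.order = order
        self.table: dict[int, list[int]] = {}
        self.total_events = 0
        self._packed: tuple[np.ndarray, np.ndarray] | None = None

    def increment(self, context: int, symbol: int, count: int = 1) -> None:
        row = self.table.get(context)
        if row is None:
            row = [0, 0, 0, 0]
            self.table[context] = row
        row[symbol] += count
        self.total_events += count
        self._packed = None

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic packed view: sorted context keys + (n, 4) count matrix."""
        if self._packed is None:
            keys = np.fromiter(self.table.keys(), dtype=np.int64, count=len(self.table))
            order_idx = np.argsort(keys, kind="stable")
            keys = keys[order_idx]
            counts = np.zeros((keys.size, 4), dtype=np.int64)
            for i, k in enumerate(keys):
                counts[i, :] = self.table[int(k)]
            self._packed = (keys, counts)
        return self._packed

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FCMCounts):
            return NotImplemented
        return self.order == other.order and self.table == other.table


def _count_events(counts: FCMCounts, syms: np.ndarray, k: int) -> None:
    n = syms.size
    if n < k + 1:
        return
    s64 = syms.astype(np.int64)
    if k == 0:
        combined = s64
    else:
        windows = np.lib.stride_tricks.sliding_window_view(s64, k)[:-1]
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        contexts = windows @ powers
        combined = contexts * 4 + s64[k:]
    uniq, cnt = np.unique(combined, return_counts=True)
    for key, c in zip(uniq.tolist(), cnt.tolist()):
        counts.increment(key >> 2, key & 3, c)


def train_fcm(config: FCMConfig, sequences: Iterable[SequenceRecord]) -> FCMCounts:
    """Count context->symbol events over the training records.

    For every position i >= order within each record the event
    (context ending at i-1, symbol at i) is counted once.  Contexts never
    cross record boundaries.  With ``use_inverted_repeats`` the
    reverse-complement event of every (k+1)-mer is counted as well, which is
    equivalent to additionally training on each record's reverse complement.
    """
    counts = FCMCounts(config.order)
    for rec in sequences:
        _count_events(counts, rec.symbols, config.order)
        if config.use_inverted_repeats:
            _count_events(counts, (3 - rec.symbols[::-1]).astype(np.int8), config.order)
    counts.as_arrays()  # freeze the deterministic view
    return counts


def context_distribution(counts: FCMCounts, alpha: float, context: int) -> np.ndarray:
    """Smoothed conditional distribution P(. | context); sums to 1."""
    row = counts.table.get(context)
    if row is None:
        return np.full(4, 0.25)
    arr = np.asarray(row, dtype=np.float64)
    return (arr + alpha) / (arr.sum() + 4.0 * alpha)


def fcm_probability(counts: FCMCounts, config: FCMConfig, context: int, symbol: int) -> float:
    """(n(context,symbol) + alpha) / (N(context) + 4 alpha); unseen context -> 1/4."""
    row = counts.table.get(context)
    if row is None:
        return 0.25
    total = row[0] + row[1] + row[2] + row[3]
    return (row[symbol] + config.alpha) / (total + 4.0 * config.alpha)


@dataclass
class STMMState:
    """Mutable per-target state of one STMM.

    ``history`` is the packed edited context; ``filled`` counts symbols seen
    since the last reset (warm-up ends at ``order``); ``window_flags`` is a
    circular buffer marking positions (mod window) at which an edit was
    spent, and ``substitutions_used`` is its running sum.
    """

    config: STMMConfig
    history: int = 0
    filled: int = 0
    substitutions_used: int = 0
    position: int = 0
    window_flags: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.window_flags:
            self.window_flags = [0] * self.config.window

    def reset(self) -> None:
        self.history = 0
        self.filled = 0
        self.substitutions_used = 0
        self.position = 0
        self.window_flags = [0] * self.config.window


def stmm_next(
    state: STMMState,
    counts: FCMCounts,
    actual_symbol: int,
) -> tuple[float, STMMState]:
    """Advance one STMM step: probability of the observed symbol, then update.

    During warm-up (fewer than ``order`` symbols since reset) the probability
    is uniform and the observed symbol is recorded.  Afterwards the
    probability comes from the shared count table under the *edited* history;
    if the observed symbol differs from the argmax prediction (ties broken
    toward the lowest symbol index) and the sliding-window substitution
    budget permits, the argmax symbol is recorded instead and one unit of
    budget is spent.
    """
    cfg = state.config
    k = cfg.order
    mask = (1 << (2 * k)) - 1 if k > 0 else 0

    # slide the window: the slot ``window`` positions back leaves scope
    slot = state.position % cfg.window
    state.substitutions_used -= state.window_flags[slot]
    state.window_flags[slot] = 0

    if state.filled < k:
        prob = 0.25
        recorded = actual_symbol
    else:
        row = counts.table.get(state.history)
        if row is None:
            prob = 0.25
            best = 0
        else:
            total = row[0] + row[1] + row[2] + row[3]
            prob = (row[actual_symbol] + cfg.alpha) / (total + 4.0 * cfg.alpha)
            best = max(range(4), key=lambda s: (row[s], -s))
        if actual_symbol != best and state.substitutions_used < cfg.max_substitutions:
            recorded = best
            state.window_flags[slot] = 1
            state.substitutions_used += 1
        else:
            recorded = actual_symbol

    state.history = ((state.history << 2) | recorded) & mask if k else 0
    state.filled += 1
    state.position += 1
    return prob, state
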