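"""Order-k finite-context (Markov) models of DNA sequences.

The model is trained once, by counting, on a reference sequence and is
strictly static afterwards: every probability served while profiling a
target uses exclusively the reference counts.  The next-symbol probability
for symbol ``s`` in context ``c`` is the additively smoothed estimator

    P(s | c) = (N(s|c) + alpha) / (N(c) + 4*alpha)

where ``N(s|c)`` is the number of times ``s`` followed the k-symbol
context ``c`` in the reference and ``N(c)`` is the total number of events
for that context.  With the default ``alpha = 0.001`` the estimator
behaves approximately as a maximum-likelihood estimator while remaining
strictly positive.  The code length of a symbol is ``-log2 P(s|c)`` bits;
an entirely unseen context therefore costs exactly 2 bits per symbol.

Counts are stored in a dense ``4^k x 4`` table for k <= 12 and in sorted
sparse key arrays above that (4^28 dense entries would be infeasible);
the two representations are value-identical.
"""

from __future__ import annotations

import json

import numpy as np

from .sequence_io import Sequence, _BYTE_TO_CODE

K_MIN, K_MAX = 1, 28
DENSE_K_MAX = 12
DEFAULT_ALPHA = 0.001

_SERIAL_VERSION = 1


def context_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 context codes and next symbols for positions k..n-1.

    ``ctx[m]`` encodes ``codes[m:m+k]`` with the leftmost symbol most
    significant; ``sym[m] = codes[k+m]``.
    """
    n = len(codes)
    if n <= k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
    m = n - k
    ctx = np.zeros(m, dtype=np.int64)
    for j in range(k):
        ctx *= 4
        ctx += codes[j : j + m]
    return ctx, codes[k:]


def _encode_context(context: str, k: int) -> int:
    if len(context) != k:
        raise ValueError(f"context must have exactly {k} symbols, got {len(context)}")
    arr = _BYTE_TO_CODE[np.frombuffer(context.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        raise ValueError(f"context {context!r} contains non-ACGT symbols")
    code = 0
    for c in arr:
        code = code * 4 + int(c)
    return code


def _encode_symbol(symbol: str) -> int:
    s = _BYTE_TO_CODE[ord(symbol)]
    if s > 3:
        raise ValueError(f"symbol must be one of ACGT, got {symbol!r}")
    return int(s)


class FCModel:
    """A trained order-k finite-context model of a reference sequence."""

    def __init__(self, k: int, alpha: float = DEFAULT_ALPHA, reference_name: str = ""):
        if not (K_MIN <= k <= K_MAX):
            raise ValueError(f"model depth k must be in [{K_MIN},{K_MAX}], got {k}")
        if alpha <= 0:
            raise ValueError(f"alpha must be positive, got {alpha}")
        self.k = k
        self.alpha = float(alpha)
        self.reference_name = reference_name
        self.n_events = 0
        self._dense: np.ndarray | None = None  # (4^k, 4) counts
        self._dense_totals: np.ndarray | None = None
        # sparse: sorted event keys (ctx*4+sym) and context keys
        self._event_keys = np.empty(0, dtype=np.int64)
        self._event_counts = np.empty(0, dtype=np.int64)
        self._ctx_keys = np.empty(0, dtype=np.int64)
        self._ctx_totals = np.empty(0, dtype=np.int64)

    @property
    def is_dense(self) -> bool:
        return self._dense is not None

    # -- training ---------------------------------------------------------

    def _train(self, codes: np.ndarray) -> None:
        ctx, sym = context_codes(codes, self.k)
        self.n_events = len(ctx)
        if self.k <= DENSE_K_MAX:
            events = ctx * 4 + sym
            table = np.bincount(events, minlength=4 ** (self.k + 1))
            self._dense = table.reshape(4**self.k, 4)
            self._dense_totals = self._dense.sum(axis=1)
        else:
            events = ctx * 4 + sym
            self._event_keys, self._event_counts = np.unique(events, return_counts=True)
            self._ctx_keys, self._ctx_totals = np.unique(ctx, return_counts=True)

    # -- vectorised queries ------------------------------------------------

    @staticmethod
    def _sparse_lookup(keys: np.ndarray, vals: np.ndarray, query: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(keys, query)
        idx_c = np.minimum(idx, len(keys) - 1) if len(keys) else idx
        if len(keys) == 0:
            return np.zeros(len(query), dtype=np.int64)
        found = keys[idx_c] == query
        out = np.where(found, vals[idx_c], 0)
        return out

    def counts_and_totals(
        self, ctx: np.ndarray, sym: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Event counts N(s|c) and context totals N(c) for code arrays."""
        if self._dense is not None:
            return self._dense[ctx, sym], self._dense_totals[ctx]
        counts = self._sparse_lookup(self._event_keys, self._event_counts, ctx * 4 + sym)
        totals = self._sparse_lookup(self._ctx_keys, self._ctx_totals, ctx)
        return counts, totals

    def code_lengths(self, ctx: np.ndarray, sym: np.ndarray) -> np.ndarray:
        """Per-event code lengths -log2 P(s|c) in bits (vectorised)."""
        counts, totals = self.counts_and_totals(ctx, sym)
        a = self.alpha
        p = (counts + a) / (totals + 4 * a)
        return -np.log2(p)

    # -- scalar API ---------------------------------------------------------

    def count(self, context: str, symbol: str) -> int:
        """Training count N(symbol | context)."""
        c = np.array([_encode_context(context, self.k)], dtype=np.int64)
        s = np.array([_encode_symbol(symbol)], dtype=np.uint8)
        return int(self.counts_and_totals(c, s)[0][0])

    def context_total(self, context: str) -> int:
        """Total training events N(context)."""
        c = np.array([_encode_context(context, self.k)], dtype=np.int64)
        s = np.zeros(1, dtype=np.uint8)
        return int(self.counts_and_totals(c, s)[1][0])

    def probability(self, context: str, symbol: str) -> float:
        """Estimated P(symbol | context); strictly positive."""
        n = self.count(context, symbol)
        t = self.context_total(context)
        return (n + self.alpha) / (t + 4 * self.alpha)

    def code_length(self, context: str, symbol: str) -> float:
        """Bits needed to encode ``symbol`` in ``context``: -log2 P."""
        return float(-np.log2(self.probability(context, symbol)))

    # -- serialization -------------------------------------------------------

    def _sparse_items(self) -> tuple[list[int], list[int]]:
        if self._dense is not None:
            flat = self._dense.ravel()
            nz = np.flatnonzero(flat)
            return nz.tolist(), flat[nz].tolist()
        return self._event_keys.tolist(), self._event_counts.tolist()

    def to_json(self, path: str) -> None:
        """Save the model (k, alpha, nonzero counts) as versioned JSON."""
        keys, counts = self._sparse_items()
        doc = {
            "format": "rearrmap-fcm",
            "version": _SERIAL_VERSION,
            "k": self.k,
            "alpha": self.alpha,
            "reference_name": self.reference_name,
            "event_keys": keys,
            "event_counts": counts,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "FCModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "rearrmap-fcm" or doc.get("version") != _SERIAL_VERSION:
            raise ValueError(f"{path}: not a version-{_SERIAL_VERSION} model file")
        model = cls(doc["k"], doc["alpha"], doc.get("reference_name", ""))
        keys = np.asarray(doc["event_keys"], dtype=np.int64)
        counts = np.asarray(doc["event_counts"], dtype=np.int64)
        model.n_events = int(counts.sum())
        if model.k <= DENSE_K_MAX:
            table = np.zeros(4 ** (model.k + 1), dtype=np.int64)
            table[keys] = counts
            model._dense = table.reshape(4**model.k, 4)
            model._dense_totals = model._dense.sum(axis=1)
        else:
            model._event_keys, model._event_counts = keys, counts
            ctx = keys // 4
            uctx, inverse = np.unique(ctx, return_inverse=True)
            model._ctx_keys = uctx
            model._ctx_totals = np.bincount(inverse, weights=counts).astype(np.int64)
        return model


def train_fcm(y: Sequence, k: int, alpha: float = DEFAULT_ALPHA) -> FCModel:
    """Train an order-k model by counting all events in reference ``y``.

    A reference shorter than k+1 symbols yields an empty (uniform) model.
    """
    model = FCModel(k, alpha, reference_name=y.name)
    model._train(y.codes())
    return model
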