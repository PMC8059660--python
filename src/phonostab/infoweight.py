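"""Per-language information-content model for alignment position weighting.

Each position of a word gets a weight in [0, 1] measuring how surprising the
segment is in its context under a per-language trigram model, estimated in
both reading directions.  Recurring material — inflectional endings above
all — is predictable and so receives low weight, which keeps dictionary-form
morphology from flooding the stability counts.

The weight is min(1, mean(forward surprisal, backward surprisal) / cap) with
add-constant smoothing (default 0.5) over inventory_size + 1 outcomes and
cap = log2(inventory_size + 1), the surprisal of a uniform draw.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .wordlist import Wordlist

__all__ = ["InfoModel", "fit_info_model", "info_content", "info_profile"]

BOS = "<s>"
EOS = "</s>"


@dataclass
class InfoModel:
    """Forward/backward trigram counts for one language."""

    language_id: str
    forward: dict[tuple[str, str], Counter]
    backward: dict[tuple[str, str], Counter]
    inventory_size: int
    smoothing: float = 0.5
    _fwd_totals: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)
    _bwd_totals: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)
    _cache: dict[tuple[str, ...], np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._fwd_totals = {c: sum(v.values()) for c, v in self.forward.items()}
        self._bwd_totals = {c: sum(v.values()) for c, v in self.backward.items()}

    @property
    def cap(self) -> float:
        return math.log2(self.inventory_size + 1)

    def _prob(self, counts, totals, ctx, seg) -> float:
        c = counts.get(ctx, None)
        k = c[seg] if c is not None else 0
        total = totals.get(ctx, 0)
        denom = total + self.smoothing * (self.inventory_size + 1)
        if denom == 0:
            return 1.0 / (self.inventory_size + 1)
        return (k + self.smoothing) / denom

    def profile(self, segments: tuple[str, ...]) -> np.ndarray:
        """Info content of every position of a form (cached per form)."""
        cached = self._cache.get(segments)
        if cached is not None:
            return cached
        n = len(segments)
        fw_pad = (BOS, BOS) + segments
        bw_seq = tuple(reversed(segments))
        bw_pad = (EOS, EOS) + bw_seq
        cap = self.cap
        out = np.empty(n)
        for i in range(n):
            s_fw = -math.log2(
                self._prob(self.forward, self._fwd_totals, (fw_pad[i], fw_pad[i + 1]), segments[i])
            )
            j = n - 1 - i  # position in the reversed sequence
            s_bw = -math.log2(
                self._prob(self.backward, self._bwd_totals, (bw_pad[j], bw_pad[j + 1]), bw_seq[j])
            )
            out[i] = min(1.0, 0.5 * (s_fw + s_bw) / cap)
        self._cache[segments] = out
        return out


def fit_info_model(
    wordlist: Wordlist, language: str, smoothing: float = 0.5
) -> InfoModel:
    """Fit the forward/backward trigram model from one language's forms."""
    forms = [f for _, f in wordlist.forms_for(language=language)]
    if not forms:
        raise KeyError(f"no forms for language {language!r}")
    forward: dict[tuple[str, str], Counter] = defaultdict(Counter)
    backward: dict[tuple[str, str], Counter] = defaultdict(Counter)
    inventory: set[str] = set()
    for f in forms:
        segs = f.segments
        inventory.update(segs)
        fw = (BOS, BOS) + segs
        for i in range(len(segs)):
            forward[(fw[i], fw[i + 1])][segs[i]] += 1
        rev = tuple(reversed(segs))
        bw = (EOS, EOS) + rev
        for i in range(len(rev)):
            backward[(bw[i], bw[i + 1])][rev[i]] += 1
    return InfoModel(
        language_id=language,
        forward=dict(forward),
        backward=dict(backward),
        inventory_size=max(1, len(inventory)),
        smoothing=smoothing,
    )


def info_content(model: InfoModel, segments: tuple[str, ...], position: int) -> float:
    """Information weight in [0, 1] of one position of a segmented form."""
    if not 0 <= position < len(segments):
        raise IndexError(f"position {position} out of range for {segments}")
    return float(model.profile(tuple(segments))[position])


def info_profile(model: InfoModel, segments: tuple[str, ...]) -> np.ndarray:
    """Vector of info weights for a whole form."""
    return model.profile(tuple(segments))
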