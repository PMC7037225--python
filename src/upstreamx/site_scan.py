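"""MATCH-style PWM scanning of promoter sequences.

Scoring model
-------------
For a matrix with per-position base frequencies f(i, b) the information
vector is

    I(i) = sum_b f(i, b) * ln(4 * f(i, b))

(natural log; I(i) >= 0, zero iff the column is uniform). A window
b_1..b_L scores

    raw = sum_i I(i) * f(i, b_i)

and the matrix similarity score normalizes raw into [0, 1]:

    mss = (raw - Min) / (Max - Min)

where Min/Max minimize/maximize raw over base choices per position. The
core similarity score (css) is the same quantity restricted to the core:
the contiguous block of ``core_length`` (default 5) positions with maximal
summed information content, leftmost on ties. Windows containing N are
skipped (no hit). Both strands are scanned; a reverse-strand hit reports
the start of the matched window in forward-strand coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import BASE_INDEX, PromoterRecord, Pwm, reverse_complement

logger = logging.getLogger("upstreamx")

DEFAULT_MSS_CUTOFF = 0.85
DEFAULT_CSS_CUTOFF = 0.90


@dataclass(frozen=True)
class SiteHit:
    """One PWM match on one promoter (forward-strand coordinates)."""

    gene_id: str
    pwm_name: str
    start: int
    strand: str  # '+' or '-'
    mss: float
    css: float

    @property
    def sort_key(self):
        return (self.gene_id, self.pwm_name, self.start, self.strand)


class ScoreModel:
    """Precomputed scoring state for one PWM.

    Attributes
    ----------
    weights : (L, 4) array, I(i) * f(i, b)
    information : (L,) array, I(i)
    core_start : leftmost start of the most informative ``core_length`` block
    """

    def __init__(self, pwm: Pwm):
        self.pwm = pwm
        f = pwm.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            ln_term = np.where(f > 0, np.log(4.0 * f), 0.0)
        self.information = np.sum(f * ln_term, axis=1)
        self.weights = self.information[:, None] * f
        self.min_by_pos = self.weights.min(axis=1)
        self.max_by_pos = self.weights.max(axis=1)

        L = len(pwm)
        k = min(pwm.core_length, L)
        block_info = np.array(
            [self.information[s:s + k].sum() for s in range(L - k + 1)]
        )
        self.core_start = int(np.argmax(block_info))  # argmax -> leftmost tie
        self.core_len = k

    def _mss(self, idx: np.ndarray, pos: slice | None = None) -> np.ndarray:
        """Score encoded windows. idx: (n_windows, L) base indices in 0..3."""
        w = self.weights if pos is None else self.weights[pos]
        lo = (self.min_by_pos if pos is None else self.min_by_pos[pos]).sum()
        hi = (self.max_by_pos if pos is None else self.max_by_pos[pos]).sum()
        raw = w[np.arange(w.shape[0])[None, :], idx].sum(axis=1)
        if hi - lo <= 0:
            return np.ones_like(raw)
        return (raw - lo) / (hi - lo)

    def score_windows(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(mss, css) for encoded windows (n, L); caller excludes N windows."""
        core = slice(self.core_start, self.core_start + self.core_len)
        return self._mss(idx), self._mss(idx[:, core], core)


def match_score(pwm: Pwm, window: str) -> tuple[float, float]:
    """Score a single window; returns (mss, css).

    A window containing N (or any non-ACGT character) returns the no-hit
    sentinel (nan, nan).
    """
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    window = window.upper()
    if any(c not in BASE_INDEX for c in window):
        return (float("nan"), float("nan"))
    model = ScoreModel(pwm)
    idx = np.array([[BASE_INDEX[c] for c in window]])
    mss, css = model.score_windows(idx)
    return float(mss[0]), float(css[0])


def _encode(seq: str) -> np.ndarray:
    """Encode DNA as 0..3, with 4 for N (marks windows to skip)."""
    table = np.full(128, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(model: ScoreModel, enc: np.ndarray,
                     mss_cutoff: float, css_cutoff: float,
                     ) -> list[tuple[int, float, float]]:
    L = len(model.pwm)
    n = len(enc) - L + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = ~(windows == 4).any(axis=1)
    if not valid.any():
        return []
    idx = windows[valid].astype(np.intp)
    mss, css = model.score_windows(idx)
    starts = np.nonzero(valid)[0]
    keep = (mss >= mss_cutoff) & (css >= css_cutoff)
    return [(int(s), float(m), float(c))
            for s, m, c in zip(starts[keep], mss[keep], css[keep])]


def scan_promoters(promoters: Sequence[PromoterRecord],
                   pwms: Sequence[Pwm],
                   mss_cutoff: float = DEFAULT_MSS_CUTOFF,
                   css_cutoff: float = DEFAULT_CSS_CUTOFF,
                   ) -> list[SiteHit]:
    """Scan every promoter with every PWM on both strands.

    Hits are windows with mss >= mss_cutoff and css >= css_cutoff, sorted by
    (gene, pwm, start, strand). Reverse-strand windows are the reverse
    complement scored against the same matrix, reported at their
    forward-strand start.
    """
    if not (0 <= mss_cutoff <= 1 and 0 <= css_cutoff <= 1):
        raise ValueError("cutoffs must be in [0, 1]")
    hits: list[SiteHit] = []
    models = [ScoreModel(p) for p in pwms]
    for prom in promoters:
        enc_fwd = _encode(prom.sequence)
        enc_rev = _encode(reverse_complement(prom.sequence))
        plen = len(prom.sequence)
        for model in models:
            L = len(model.pwm)
            if L > plen:
                logger.warning(
                    "matrix %s (length %d) longer than promoter %s (%d bp); "
                    "no hits", model.pwm.name, L, prom.gene_id, plen,
                )
                continue
            for start, mss, css in _scan_one_strand(
                    model, enc_fwd, mss_cutoff, css_cutoff):
                hits.append(SiteHit(prom.gene_id, model.pwm.name,
                                    start, "+", mss, css))
            for rstart, mss, css in _scan_one_strand(
                    model, enc_rev, mss_cutoff, css_cutoff):
                hits.append(SiteHit(prom.gene_id, model.pwm.name,
                                    plen - L - rstart, "-", mss, css))
    hits.sort(key=lambda h: h.sort_key)
    return hits


def hits_to_frame(hits: Iterable[SiteHit],
                  pwm_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    rows = [
        {
            "gene_id": h.gene_id,
            "pwm": h.pwm_name,
            "start": h.start,
            "end": h.start + (pwm_lengths or {}).get(h.pwm_name, 0)
            if pwm_lengths else None,
            "strand": h.strand,
            "mss": h.mss,
            "css": h.css,
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "pwm", "start", "end",
                                     "strand", "mss", "css"])
    if pwm_lengths is None:
        df = df.drop(columns=["end"])
    return df
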