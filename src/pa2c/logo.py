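"""Sequence-logo arithmetic: per-column information content and letter heights.

Implements the Schneider-Stephens formulation: for column j over an
alphabet of S letters, IC_j = log2(S) - H_j - e(n), where H_j is the
column's Shannon entropy in bits and e(n) = (S-1) / (2 ln(2) n) is the
small-sample correction for n observed (non-gap) letters.  Letter height
is frequency x IC.  Gaps are excluded from both the frequencies and n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pa2c.core import Pa2cError

PROTEIN_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = tuple("ACGT")

#: blocks smaller than this default to the small-sample correction
SMALL_SAMPLE_N = 50


class LogoError(Pa2cError):
    pass


@dataclass
class LogoMatrix:
    """Per-column frequencies, information content (bits) and letter heights."""

    frequencies: pd.DataFrame  # columns x letters, rows sum to 1 (or 0 if all-gap)
    information: np.ndarray    # bits per column
    heights: pd.DataFrame      # frequency x IC
    alphabet: tuple[str, ...]

    def to_tsv(self, path) -> None:
        out = self.frequencies.copy()
        out.columns = [f"freq_{c}" for c in out.columns]
        for letter in self.alphabet:
            out[f"height_{letter}"] = self.heights[letter]
        out.insert(0, "ic_bits", self.information)
        out.to_csv(path, sep="\t", float_format="%.6g", index_label="column")


def logo_from_block(
    sequences: list[str],
    alphabet: str = "protein",
    small_sample_correction: bool | None = None,
) -> LogoMatrix:
    """Build logo statistics from an aligned block of equal-length strings.

    ``small_sample_correction=None`` enables the correction automatically
    for blocks of fewer than 50 sequences.  IC is clamped at zero.
    """
    if not sequences:
        raise LogoError("empty alignment block")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise LogoError("ragged alignment block")
    letters = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    s_size = len(letters)
    if small_sample_correction is None:
        small_sample_correction = len(sequences) < SMALL_SAMPLE_N

    freqs = np.zeros((width, s_size))
    ic = np.zeros(width)
    index = {c: k for k, c in enumerate(letters)}
    for j in range(width):
        counts = np.zeros(s_size)
        for seq in sequences:
            c = seq[j].upper()
            if c == "-":
                continue
            if c in index:
                counts[index[c]] += 1
            # ambiguity letters (X/N) are ignored, like gaps
        n = counts.sum()
        if n == 0:
            continue
        p = counts / n
        entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        correction = (s_size - 1) / (2 * math.log(2) * n) if small_sample_correction else 0.0
        ic[j] = max(0.0, math.log2(s_size) - entropy - correction)
        freqs[j] = p

    freq_df = pd.DataFrame(freqs, columns=list(letters))
    heights = freq_df.mul(ic, axis=0)
    return LogoMatrix(
        frequencies=freq_df, information=ic, heights=heights, alphabet=letters
    )
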