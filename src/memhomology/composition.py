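"""Residue composition models shared across the package.

Two fixed tables drive both the synthetic generator and the background
models of the profile and motif statistics:

* ``TMS_FREQS`` — a hydrophobic-biased distribution with 80% of its mass on
  {I, L, V, F, A, M, W, G, C}.  This reproduces the compositional bias of
  membrane-embedded segments that makes naive alignment statistics
  anti-conservative, which is exactly what the shuffle nulls are for.
* ``LOOP_FREQS`` — Robinson–Robinson average protein composition, used for
  soluble loops and as the general-purpose background distribution.
"""

from __future__ import annotations

import numpy as np

from .core_io import AA20

TMS_FREQS: dict[str, float] = {
    # hydrophobic core: 0.80 total
    "I": 0.14, "L": 0.16, "V": 0.12, "F": 0.10, "A": 0.12,
    "M": 0.05, "W": 0.03, "G": 0.06, "C": 0.02,
    # the rest: 0.20 total
    "T": 0.035, "S": 0.035, "Y": 0.02, "P": 0.015, "H": 0.01,
    "N": 0.015, "Q": 0.015, "D": 0.01, "E": 0.01, "K": 0.015, "R": 0.02,
}

#: Robinson & Robinson amino-acid frequencies (average protein composition).
LOOP_FREQS: dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

BACKGROUND = LOOP_FREQS  # alias: the null model for motifs and profiles


def freqs_as_array(freqs: dict[str, float]) -> np.ndarray:
    """Frequencies as a normalised vector in AA20 order."""
    v = np.array([freqs[a] for a in AA20], dtype=float)
    return v / v.sum()


TMS_VECTOR = freqs_as_array(TMS_FREQS)
LOOP_VECTOR = freqs_as_array(LOOP_FREQS)
BACKGROUND_VECTOR = LOOP_VECTOR


def sample_residues(n: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    """Draw ``n`` residues i.i.d. from a frequency vector in AA20 order."""
    idx = rng.choice(len(AA20), size=n, p=freqs)
    return "".join(AA20[i] for i in idx)
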