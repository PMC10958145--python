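"""Empirical amino-acid replacement models (JTT built in, pluggable).

The model is the usual general time-reversible parameterisation
Q_ij = s_ij * pi_j with a symmetric exchangeability matrix ``s`` and
stationary frequencies ``pi``, normalised to one expected substitution
per site per unit branch length.  State order is the PAML convention
A R N D C Q E G H I L K M F P S T W Y V.
"""

from __future__ import annotations

import numpy as np

from .codon import ReversibleEigen

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# Jones-Taylor-Thornton (1992) exchangeabilities, lower triangle in
# AA_ORDER, and the accompanying stationary frequencies.
_JTT_LOWER = """
58
54 81
56 57 105
179 27 36 30
35 54 15 194 378
475 9 11 298 45 16
113 310 29 137 328 22 38
646 44 5 74 101 64 126 20
17 528 34 86 58 81 391 47 12
263 30 10 15 503 232 8 70 16 10
49 767 130 112 11 7 26 15 4 15 59
38 4 46 31 9 5 59 69 17 23 7 31
78 14 223 42 115 209 62 323 26 597 9 72 292
43 4 164 53 51 18 24 20 119 26 12 9 181 18
5 18 30 32 10 7 45 23 6 6 27 14 5 24 201
33 55 8 47 16 56 45 33 40 115 73 46 8 573 11 229
21 479 89 10 40 245 9 32 961 14 388 248 102 59 25 52 24
180 65 4 21 47 103 10 8 14 43 16 29 226 24 18 323 17 92
12 53 536 62 285 118 6 10 23 477 35 63 38 12 21 112 71 25 16
"""

_JTT_FREQS = np.array([
    0.0767479233, 0.0516909483, 0.0426449574, 0.0515439485, 0.0198029802,
    0.0407519592, 0.0618299382, 0.0731519268, 0.0229439771, 0.0537609462,
    0.0919039081, 0.0586759413, 0.0238259762, 0.0401259599, 0.0509009491,
    0.0687649312, 0.0585649414, 0.0142609857, 0.0321019679, 0.0660049340,
])


def _parse_lower(text: str) -> np.ndarray:
    S = np.zeros((20, 20))
    rows = [r for r in text.strip().splitlines() if r.strip()]
    if len(rows) != 19:
        raise ValueError("expected 19 lower-triangle rows")
    for i, row in enumerate(rows, start=1):
        vals = [float(x) for x in row.split()]
        if len(vals) != i:
            raise ValueError(f"row {i} has {len(vals)} entries, expected {i}")
        S[i, :i] = vals
        S[:i, i] = vals
    return S


class AminoAcidModel:
    """Reversible 20-state replacement model with precomputed spectrum."""

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray,
                 name: str = "custom"):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if pi.shape != (20,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-6:
            raise ValueError("frequencies must be 20 values summing to 1")
        self.name = name
        self.S = S
        self.pi = pi / pi.sum()
        Q = S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(self.pi @ np.diag(Q))
        self.Q = Q / rate
        self.eigen = ReversibleEigen(self.Q, self.pi)

    def P(self, t: float) -> np.ndarray:
        """Transition probabilities after branch length t (subs/site)."""
        return self.eigen.P(t)

    def __repr__(self):
        return f"AminoAcidModel({self.name})"


def jtt() -> AminoAcidModel:
    """The Jones-Taylor-Thornton (1992) model with its original frequencies."""
    return AminoAcidModel(_parse_lower(_JTT_LOWER), _JTT_FREQS, name="JTT")


def encode_protein(seqs: dict[str, str] | list[str], taxa=None) -> tuple[list[str], np.ndarray]:
    """Encode protein sequences to an (n_taxa, n_sites) index matrix.

    Non-standard symbols (gap, X, U, ...) become -1 (missing)."""
    if isinstance(seqs, dict):
        taxa = list(seqs)
        rows = [seqs[t] for t in taxa]
    else:
        rows = list(seqs)
        taxa = list(taxa) if taxa is not None else [f"t{i}" for i in range(len(rows))]
    n = len(rows[0])
    if any(len(r) != n for r in rows):
        raise ValueError("protein sequences must have equal length")
    mat = np.full((len(rows), n), -1, dtype=int)
    for i, r in enumerate(rows):
        for j, a in enumerate(r.upper()):
            mat[i, j] = AA_INDEX.get(a, -1)
    return taxa, mat
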