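"""Motif sequence properties: Kyte-Doolittle hydropathy and symmetry score."""

from __future__ import annotations

#: Kyte-Doolittle hydropathy scale (one-letter code -> value).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5,
    "M": 1.9, "A": 1.8, "G": -0.4, "T": -0.7, "S": -0.8,
    "W": -0.9, "Y": -1.3, "P": -1.6, "H": -3.2, "E": -3.5,
    "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}


def _profile(sequence: str) -> list[float]:
    try:
        return [KYTE_DOOLITTLE[c] for c in sequence.upper()]
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in "
                         f"{sequence!r}") from None


def average_hydropathy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy over the motif residues."""
    if not sequence:
        raise ValueError("empty sequence")
    values = _profile(sequence)
    return sum(values) / len(values)


def symmetry_score(sequence: str) -> float:
    """Hydropathy-profile symmetry of a peptide.

    score = sum_{n=1..a} |H_n - H_{x-n+1}| / a, with x the motif length and
    a = x // 2.  Zero iff the hydropathy profile reads the same from both
    ends; the middle residue of an odd-length motif does not contribute.
    """
    x = len(sequence)
    if x < 2:
        raise ValueError("symmetry score requires length >= 2")
    h = _profile(sequence)
    a = x // 2
    return sum(abs(h[n - 1] - h[x - n]) for n in range(1, a + 1)) / a
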