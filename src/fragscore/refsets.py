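"""Positive and random benchmark reference sets for domain-motif interfaces.

Random (non-binding) references are built two ways:

* **Miyata mutagenesis** — the key (non-wildcard) positions of a motif are
  located by aligning the motif sequence to its class regular expression, and
  one or two of them are substituted by the amino acid at maximal Miyata
  distance, i.e. the most dissimilar residue in the volume/polarity plane.
* **Shuffled pairings** — motif and domain assignments of known instances are
  permuted such that no motif ends up with a domain whose type could actually
  bind it (cognate avoidance, including across classes sharing a domain type).

The 20x20 Miyata distance table is shipped as static data; it is the pairwise
Euclidean distance over polarity and volume differences, each normalized by
the standard deviation of the 190 pairwise differences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from Bio import Align

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Miyata (1979) distances, frozen from the volume/polarity formula.
_MIYATA_ROWS = {
    "A": (0.0000, 1.3925, 2.3676, 2.4646, 3.2286, 0.9145, 2.1692, 2.6857, 2.9566, 2.7579, 2.4214, 1.7776, 0.0636, 1.9237, 2.9229, 0.5107, 0.9022, 1.8473, 4.2293, 3.1762),
    "C": (1.3925, 0.0000, 3.4765, 3.2553, 2.2422, 2.2172, 2.5649, 1.6335, 3.2692, 1.6512, 1.4561, 2.8276, 1.3306, 2.4762, 3.0648, 1.8407, 1.4475, 0.8630, 3.3426, 2.3764),
    "D": (2.3676, 3.4765, 0.0000, 0.9031, 4.2674, 2.3737, 1.7154, 3.9769, 2.0469, 4.1038, 3.6941, 0.6515, 2.4004, 1.4678, 2.3413, 1.8738, 2.0496, 3.4045, 4.8761, 3.9515),
    "E": (2.4646, 3.2553, 0.9031, 0.0000, 3.5859, 2.7831, 0.9583, 3.3901, 1.1444, 3.5253, 3.1253, 0.8492, 2.4752, 0.8364, 1.4547, 2.0644, 1.8303, 2.9667, 4.0771, 3.2198),
    "F": (3.2286, 2.2422, 4.2674, 3.5859, 0.0000, 4.1423, 2.6276, 0.6103, 2.8526, 0.6260, 0.8182, 3.6986, 3.1697, 2.8109, 2.4676, 3.4474, 2.5965, 1.4323, 1.1083, 0.4779),
    "G": (0.9145, 2.2172, 2.3737, 2.7831, 4.1423, 0.0000, 2.7797, 3.5993, 3.5359, 3.6694, 3.3359, 1.9558, 0.9747, 2.4826, 3.5848, 0.8479, 1.6959, 2.7580, 5.1325, 4.0775),
    "H": (2.1692, 2.5649, 1.7154, 0.9583, 2.6276, 2.7797, 0.0000, 2.4494, 0.7880, 2.5864, 2.1942, 1.2888, 2.1549, 0.3230, 0.8151, 1.9415, 1.3156, 2.1148, 3.1618, 2.2675),
    "I": (2.6857, 1.6335, 3.9769, 3.3901, 0.6103, 3.5993, 2.4494, 0.0000, 2.8370, 0.1391, 0.2900, 3.3698, 2.6248, 2.5703, 2.4856, 2.9512, 2.1437, 0.8492, 1.7173, 0.8618),
    "K": (2.9566, 3.2692, 2.0469, 1.1444, 2.8526, 3.5359, 0.7880, 2.8370, 0.0000, 2.9756, 2.6274, 1.8363, 2.9428, 1.0554, 0.3983, 2.7094, 2.0995, 2.7018, 3.1106, 2.4150),
    "L": (2.7579, 1.6512, 4.1038, 3.5253, 0.6260, 3.6694, 2.5864, 0.1391, 2.9756, 0.0000, 0.4098, 3.4928, 2.6963, 2.7035, 2.6231, 3.0405, 2.2479, 0.9114, 1.7303, 0.9439),
    "M": (2.4214, 1.4561, 3.6941, 3.1253, 0.8182, 3.3359, 2.1942, 0.2900, 2.6274, 0.4098, 0.0000, 3.0834, 2.3615, 2.2996, 2.2924, 2.6708, 1.8553, 0.6173, 1.8942, 0.9303),
    "N": (1.7776, 2.8276, 0.6515, 0.8492, 3.6986, 1.9558, 1.2888, 3.3698, 1.8363, 3.4928, 3.0834, 0.0000, 1.8030, 0.9851, 2.0410, 1.3130, 1.3981, 2.7646, 4.3859, 3.4163),
    "P": (0.0636, 1.3306, 2.4004, 2.4752, 3.1697, 0.9747, 2.1549, 2.6248, 2.9428, 2.6963, 2.3615, 1.8030, 0.0000, 1.9160, 2.9008, 0.5564, 0.8738, 1.7855, 4.1740, 3.1216),
    "Q": (1.9237, 2.4762, 1.4678, 0.8364, 2.8109, 2.4826, 0.3230, 2.5703, 1.0554, 2.7035, 2.2996, 0.9851, 1.9160, 0.0000, 1.1335, 1.6540, 1.1235, 2.1324, 3.4192, 2.4839),
    "R": (2.9229, 3.0648, 2.3413, 1.4547, 2.4676, 3.5848, 0.8151, 2.4856, 0.3983, 2.6231, 2.2924, 2.0410, 2.9008, 1.1335, 0.0000, 2.7409, 2.0318, 2.4285, 2.7158, 2.0234),
    "S": (0.5107, 1.8407, 1.8738, 2.0644, 3.4474, 0.8479, 1.9415, 2.9512, 2.7094, 3.0405, 2.6708, 1.3130, 0.5564, 1.6540, 2.7409, 0.0000, 0.8875, 2.1503, 4.3805, 3.3271),
    "T": (0.9022, 1.4475, 2.0496, 1.8303, 2.5965, 1.6959, 1.3156, 2.1437, 2.0995, 2.2479, 1.8553, 1.3981, 0.8738, 1.1235, 2.0318, 0.8875, 0.0000, 1.4188, 3.4980, 2.4472),
    "V": (1.8473, 0.8630, 3.4045, 2.9667, 1.4323, 2.7580, 2.1148, 0.8492, 2.7018, 0.9114, 0.6173, 2.7646, 1.7855, 2.1324, 2.4285, 2.1503, 1.4188, 0.0000, 2.5102, 1.5177),
    "W": (4.2293, 3.3426, 4.8761, 4.0771, 1.1083, 5.1325, 3.1618, 1.7173, 3.1106, 1.7303, 1.8942, 4.3859, 4.1740, 3.4192, 2.7158, 4.3805, 3.4980, 2.5102, 0.0000, 1.0554),
    "Y": (3.1762, 2.3764, 3.9515, 3.2198, 0.4779, 4.0775, 2.2675, 0.8618, 2.4150, 0.9439, 0.9303, 3.4163, 3.1216, 2.4839, 2.0234, 3.3271, 2.4472, 1.5177, 1.0554, 0.0000),
}

#: 20x20 symmetric Miyata distance matrix indexed by AMINO_ACIDS order.
MIYATA_MATRIX = np.array([_MIYATA_ROWS[a] for a in AMINO_ACIDS])


def miyata_distance(a: str, b: str) -> float:
    """Miyata distance between two one-letter amino acid codes."""
    return float(MIYATA_MATRIX[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)])


def max_miyata_substitution(residue: str) -> str:
    """Amino acid at maximal Miyata distance (ties: alphabetical)."""
    row = MIYATA_MATRIX[AMINO_ACIDS.index(residue)]
    best = row.max()
    for aa, d in zip(AMINO_ACIDS, row):  # AMINO_ACIDS is alphabetical
        if d == best:
            return aa
    raise AssertionError("unreachable")


@dataclass
class MotifClassDef:
    """One motif class: regex, cognate domain types, carried-over probability."""

    class_id: str
    regex: str
    cognate_domain_types: frozenset[str]
    motif_probability: float | None = None

    def __post_init__(self) -> None:
        re.compile(self.regex)  # must compile
        self.cognate_domain_types = frozenset(self.cognate_domain_types)


@dataclass
class DMIInstance:
    """One benchmark entry: a motif instance paired with a binding domain."""

    class_id: str
    motif_protein: str
    motif_span: tuple[int, int]
    motif_sequence: str
    domain_protein: str
    domain_span: tuple[int, int]
    domain_sequence: str
    provenance: Literal["positive", "shuffled", "mutant_1", "mutant_2"] = "positive"

    def __post_init__(self) -> None:
        for seq, span, what in ((self.motif_sequence, self.motif_span, "motif"),
                                (self.domain_sequence, self.domain_span, "domain")):
            if len(seq) != span[1] - span[0] + 1:
                raise ValueError(f"{what} sequence length {len(seq)} does not "
                                 f"match span {span}")


# ---------------------------------------------------------------------------
# key positions from the class regular expression
# ---------------------------------------------------------------------------

_QUANTIFIER = re.compile(r"(\{\d+(,\d*)?\}|[*+?])")


def _tokenize_regex(pattern: str) -> list[tuple[str, bool]]:
    """Split a motif regex into top-level (token, is_wildcard) elements.

    A token is one regex element (literal, character class, '.', or a
    parenthesized group) together with its quantifier.  Only the bare
    wildcard '.' counts as undefined; classes, literals and alternation
    groups are "defined" positions.
    """
    tokens: list[tuple[str, bool]] = []
    i = 0
    n = len(pattern)
    while i < n:
        c = pattern[i]
        if c in "^$":
            i += 1
            continue
        if c == "|":
            raise ValueError(
                "top-level alternation is not supported; wrap it in a group"
            )
        if c == "[":
            j = i + 1
            if j < n and pattern[j] == "^":
                j += 1
            if j < n and pattern[j] == "]":
                j += 1
            while j < n and pattern[j] != "]":
                if pattern[j] == "\\":
                    j += 1
                j += 1
            if j >= n:
                raise ValueError(f"unbalanced character class in {pattern!r}")
            element, wildcard = pattern[i:j + 1], False
            i = j + 1
        elif c == "(":
            depth = 0
            j = i
            while j < n:
                if pattern[j] == "\\":
                    j += 1
                elif pattern[j] == "(":
                    depth += 1
                elif pattern[j] == ")":
                    depth -= 1
                    if depth == 0:
                        break
                j += 1
            if depth != 0:
                raise ValueError(f"unbalanced group in {pattern!r}")
            element, wildcard = pattern[i:j + 1], False
            i = j + 1
        elif c == "\\":
            element, wildcard = pattern[i:i + 2], False
            i += 2
        elif c == ".":
            element, wildcard = ".", True
            i += 1
        else:
            element, wildcard = re.escape(c) if c in "{}" else c, False
            i += 1
        m = _QUANTIFIER.match(pattern, i)
        if m:
            element += m.group(0)
            i = m.end()
        tokens.append((element, wildcard))
    return tokens


def key_positions(regex: str, motif_sequence: str) -> list[int]:
    """1-based motif positions whose regex element is not a bare wildcard.

    The sequence is aligned to the regex by re-matching with every element
    wrapped in a group; every position covered by a non-wildcard element is a
    key ("defined") position.
    """
    tokens = _tokenize_regex(regex)
    grouped = "".join(f"(?P<t{i}>{element})" for i, (element, _) in enumerate(tokens))
    match = re.fullmatch(grouped, motif_sequence)
    if match is None:
        raise ValueError(
            f"sequence {motif_sequence!r} does not match regex {regex!r}"
        )
    positions: set[int] = set()
    for i, (_, wildcard) in enumerate(tokens):
        if wildcard:
            continue
        start, end = match.span(f"t{i}")
        if start == -1:
            continue
        positions.update(range(start + 1, end + 1))
    return sorted(positions)


# ---------------------------------------------------------------------------
# Miyata mutagenesis
# ---------------------------------------------------------------------------

def miyata_mutate(motif_sequence: str, positions: Sequence[int], k: int,
                  selection_policy: Literal["first", "all-subsets"] = "first"
                  ) -> str | list[str]:
    """Substitute k key residues by their maximal-Miyata-distance partner.

    With the default ``first`` policy the first k key positions (left to
    right) are mutated and a single sequence is returned; with
    ``all-subsets`` every k-subset of key positions is mutated and the list
    of mutants is returned.  Each mutant differs from the original at exactly
    k positions.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    positions = sorted(positions)
    if len(positions) < k:
        raise ValueError(f"need at least {k} key positions, got {len(positions)}")
    for p in positions:
        if not (1 <= p <= len(motif_sequence)):
            raise ValueError(f"position {p} outside sequence of length "
                             f"{len(motif_sequence)}")

    def mutate(subset: Sequence[int]) -> str:
        chars = list(motif_sequence)
        for p in subset:
            original = chars[p - 1]
            if original not in AMINO_ACIDS:
                raise ValueError(f"non-standard residue {original!r}")
            chars[p - 1] = max_miyata_substitution(original)
        return "".join(chars)

    if selection_policy == "first":
        return mutate(positions[:k])
    if selection_policy == "all-subsets":
        from itertools import combinations
        return [mutate(subset) for subset in combinations(positions, k)]
    raise ValueError(f"unknown selection policy {selection_policy!r}")


# ---------------------------------------------------------------------------
# shuffled pairings
# ---------------------------------------------------------------------------

class ShuffleError(RuntimeError):
    """No cognate-avoiding permutation found within the attempt limit."""


def shuffle_pairs(instances: Sequence[DMIInstance],
                  class_defs: dict[str, MotifClassDef],
                  seed: int, max_attempts: int = 10_000) -> list[DMIInstance]:
    """Permute domain assignments avoiding all cognate coincidences.

    A motif may not receive a domain whose type set intersects its own
    class's cognate domain types — this forbids the identity pairing and any
    cross-class pairing that shares a domain type.  Rejection resampling with
    a seeded generator; reproducible for a fixed seed.
    """
    if len(instances) < 2:
        raise ValueError("need at least two instances to shuffle")
    cognates = []
    for inst in instances:
        if inst.class_id not in class_defs:
            raise KeyError(f"no class definition for {inst.class_id!r}")
        cognates.append(class_defs[inst.class_id].cognate_domain_types)

    rng = np.random.default_rng(seed)
    n = len(instances)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        if all(not (cognates[i] & cognates[perm[i]]) for i in range(n)):
            break
    else:
        conflicts = [
            (instances[i].class_id, instances[j].class_id)
            for i in range(n) for j in range(n)
            if cognates[i] & cognates[j]
        ]
        raise ShuffleError(
            f"no valid permutation in {max_attempts} attempts; conflicting "
            f"class pairs: {sorted(set(conflicts))}"
        )

    shuffled = []
    for i in range(n):
        donor = instances[perm[i]]
        motif = instances[i]
        shuffled.append(DMIInstance(
            class_id=motif.class_id,
            motif_protein=motif.motif_protein,
            motif_span=motif.motif_span,
            motif_sequence=motif.motif_sequence,
            domain_protein=donor.domain_protein,
            domain_span=donor.domain_span,
            domain_sequence=donor.domain_sequence,
            provenance="shuffled",
        ))
    return shuffled


# ---------------------------------------------------------------------------
# sequence identity
# ---------------------------------------------------------------------------

def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identity from a global alignment with no gap penalties.

    Matches score 1, mismatches 0, gaps cost nothing; the optimal score is
    the longest-common-subsequence length, divided by the length of the
    longer sequence.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    matches = aligner.score(seq_a, seq_b)
    return float(matches) / max(len(seq_a), len(seq_b))
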