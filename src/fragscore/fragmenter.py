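"""Region annotation, sliding-window fragment design and fragment pairing.

Disordered regions of each interaction partner are tiled with overlapping
windows (default sizes 10, 20 and 30 residues, slid by half the window size);
the unfragmented disordered regions and the ordered regions complete the set.
Disordered material of one protein is paired with the ordered regions of the
other (and vice versa), and ordered regions are paired with each other, to
form the prediction jobs of the fragmentation approach.

Extension schedules grow a minimal motif or domain fragment stepwise towards
the full-length sequence, for probing how sequence context changes prediction
confidence and accuracy.

All coordinates are 1-based inclusive, matching author numbering in PDB files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

logger = logging.getLogger("fragscore")

Span = tuple[int, int]
Label = Literal["ordered", "disordered"]

DEFAULT_FRAGMENT_SIZES = (10, 20, 30)

#: An extension step that adds fewer residues than this on both termini is
#: considered minimal and the step is excluded.
MINIMAL_EXTENSION_RESIDUES = 20


@dataclass
class RegionAnnotation:
    """Ordered/disordered span annotation of one protein.

    Ordered spans may not overlap each other; a disordered span may lie inside
    an ordered span (a low-confidence loop within a domain is annotated as
    disordered *in addition* to being part of the ordered region).
    """

    protein_id: str
    length: int
    spans: list[tuple[int, int, Label]] = field(default_factory=list)
    source: Literal["manual", "suggested"] = "manual"

    def __post_init__(self) -> None:
        for start, end, label in self.spans:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"span ({start}, {end}) outside [1, {self.length}] "
                    f"for {self.protein_id}"
                )
            if label not in ("ordered", "disordered"):
                raise ValueError(f"bad label {label!r}")
        ordered = self.ordered_spans()
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"ordered spans overlap: ({s1},{e1}) and ({s2},{e2})"
                )

    def ordered_spans(self) -> list[Span]:
        return sorted((s, e) for s, e, lab in self.spans if lab == "ordered")

    def disordered_spans(self) -> list[Span]:
        return sorted((s, e) for s, e, lab in self.spans if lab == "disordered")


@dataclass(frozen=True, order=True)
class Fragment:
    """A 1-based inclusive sequence interval of one protein."""

    protein_id: str
    start: int
    end: int
    label: Label = "disordered"
    window_size: int | Literal["whole-region"] = "whole-region"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FragmentPair:
    """Two fragments from the two proteins of a PPI, submitted as one job."""

    fragment_a: Fragment
    fragment_b: Fragment
    pair_kind: Literal["disordered-ordered", "ordered-ordered"]


@dataclass(frozen=True)
class ExtensionLevel:
    """Position in the extension schedule (0 = minimal annotated fragment)."""

    motif_level: int = 0
    domain_level: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.motif_level <= 6):
            raise ValueError("motif_level must be in 0..6")
        if not (0 <= self.domain_level <= 3):
            raise ValueError("domain_level must be in 0..3")


# ---------------------------------------------------------------------------
# region suggestion
# ---------------------------------------------------------------------------

def suggest_regions(per_residue_plddt: Sequence[float], smoothing_window: int = 5,
                    cutoff: float = 70.0, protein_id: str = "") -> RegionAnnotation:
    """Propose ordered/disordered spans from a monomer pLDDT profile.

    Smoothed pLDDT >= cutoff is labelled ordered; runs shorter than the
    smoothing window are absorbed into their neighbourhood.  The result is a
    *suggestion* for human review — manual annotations always take precedence,
    because automated boundary placement that clips residues off a folded
    domain can badly mislead downstream predictions.
    """
    if len(per_residue_plddt) == 0:
        raise ValueError("pLDDT profile is empty")
    values = list(per_residue_plddt)
    n = len(values)
    w = max(1, int(smoothing_window))
    half = w // 2
    smoothed = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed.append(sum(values[lo:hi]) / (hi - lo))
    labels = ["ordered" if v >= cutoff else "disordered" for v in smoothed]

    def runs(lab: list[str]) -> list[tuple[int, int, str]]:
        out = []
        start = 0
        for i in range(1, n + 1):
            if i == n or lab[i] != lab[start]:
                out.append((start, i - 1, lab[start]))
                start = i
        return out

    # absorb short runs into the preceding (or following) run
    merged = runs(labels)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for i, (s, e, lab) in enumerate(merged):
            if e - s + 1 < w:
                neighbor = i - 1 if i > 0 else i + 1
                ns, ne, nlab = merged[neighbor]
                for j in range(s, e + 1):
                    labels[j] = nlab
                merged = runs(labels)
                changed = True
                break

    spans = [(s + 1, e + 1, lab) for s, e, lab in runs(labels)]
    return RegionAnnotation(protein_id=protein_id, length=n, spans=spans,
                            source="suggested")


# ---------------------------------------------------------------------------
# fragment tiling
# ---------------------------------------------------------------------------

def fragment_region(span: Span, sizes: Iterable[int],
                    protein_id: str = "", label: Label = "disordered"
                    ) -> list[Fragment]:
    """Tile a region with sliding windows of each size.

    For each size ``s`` a primary series starts at the span start with step
    ``s`` and an offset series starts at ``start + s/2``, so that consecutive
    windows overlap by exactly half a window.  A window that would run past
    the span end is replaced by one terminal window anchored at the end
    (dropped if it duplicates an existing window).  The whole unfragmented
    span is always included; a region shorter than ``s`` contributes only the
    whole-region fragment for that size.  Output de-duplicated, sorted by
    (start, end).
    """
    start, end = span
    if end < start:
        raise ValueError(f"invalid span {span}")
    length = end - start + 1

    seen: dict[Span, Fragment] = {}

    def add(s: int, e: int, size: int | Literal["whole-region"]) -> None:
        if (s, e) not in seen:
            seen[(s, e)] = Fragment(protein_id=protein_id, start=s, end=e,
                                    label=label, window_size=size)

    add(start, end, "whole-region")
    for size in sorted(set(int(s) for s in sizes)):
        if size <= 0:
            raise ValueError(f"fragment size must be positive, got {size}")
        if size % 2 != 0:
            raise ValueError(f"fragment size must be even, got {size} "
                             "(half-window step undefined)")
        if length < size:
            continue  # whole region already present
        for series_start in (start, start + size // 2):
            pos = series_start
            terminal_emitted = False
            while pos <= end:
                wend = pos + size - 1
                if wend > end:
                    if not terminal_emitted:
                        add(end - size + 1, end, size)
                        terminal_emitted = True
                    break
                add(pos, wend, size)
                pos += size
    return sorted(seen.values(), key=lambda f: (f.start, f.end))


def fragment_annotation(annotation: RegionAnnotation,
                        sizes: Iterable[int] = DEFAULT_FRAGMENT_SIZES
                        ) -> list[Fragment]:
    """Fragments of all disordered spans of a protein (incl. whole regions)."""
    frags: list[Fragment] = []
    for s, e in annotation.disordered_spans():
        frags.extend(fragment_region((s, e), sizes,
                                     protein_id=annotation.protein_id,
                                     label="disordered"))
    # de-duplicate across spans
    out: dict[tuple, Fragment] = {}
    for f in frags:
        out.setdefault((f.start, f.end, f.window_size), f)
    return sorted(out.values(), key=lambda f: (f.start, f.end))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _ordered_fragments(annotation: RegionAnnotation) -> list[Fragment]:
    return [Fragment(protein_id=annotation.protein_id, start=s, end=e,
                     label="ordered", window_size="whole-region")
            for s, e in annotation.ordered_spans()]


def pair_fragments(annotation_a: RegionAnnotation, annotation_b: RegionAnnotation,
                   fragments_a: Sequence[Fragment], fragments_b: Sequence[Fragment]
                   ) -> list[FragmentPair]:
    """Enumerate prediction jobs for one PPI.

    {disordered fragments and whole disordered regions of A} x {ordered
    regions of B}, the same with A and B swapped, plus {ordered A} x
    {ordered B}.  Deterministic order, no duplicates.
    """
    ordered_a = _ordered_fragments(annotation_a)
    ordered_b = _ordered_fragments(annotation_b)
    if not ordered_a:
        logger.warning("protein %s has no ordered region", annotation_a.protein_id)
    if not ordered_b:
        logger.warning("protein %s has no ordered region", annotation_b.protein_id)

    dis_a = [f for f in fragments_a if f.label == "disordered"]
    dis_b = [f for f in fragments_b if f.label == "disordered"]

    pairs: list[FragmentPair] = []
    seen: set[tuple] = set()

    def add(fa: Fragment, fb: Fragment, kind) -> None:
        key = (fa.protein_id, fa.start, fa.end, fa.window_size,
               fb.protein_id, fb.start, fb.end, fb.window_size, kind)
        if key not in seen:
            seen.add(key)
            pairs.append(FragmentPair(fragment_a=fa, fragment_b=fb, pair_kind=kind))

    for fa in dis_a:
        for fb in ordered_b:
            add(fa, fb, "disordered-ordered")
    for fb in dis_b:
        for fa in ordered_a:
            add(fb, fa, "disordered-ordered")
    for fa in ordered_a:
        for fb in ordered_b:
            add(fa, fb, "ordered-ordered")
    return pairs


# ---------------------------------------------------------------------------
# extension schedules
# ---------------------------------------------------------------------------

def _clip(span: Span, protein_length: int) -> Span:
    return (max(1, span[0]), min(protein_length, span[1]))


def _one_sided(motif_span: Span, protein_length: int) -> tuple[bool, bool]:
    """(extend_n, extend_c): a terminal fragment extends on one side only."""
    start, end = motif_span
    # at N terminus -> only C-terminal extension; at C terminus -> only N
    if start == 1 and end != protein_length:
        return (False, True)
    if end == protein_length and start != 1:
        return (True, False)
    return (True, True)


def extend_motif(motif_span: Span, level: int,
                 neighbor_domains: Sequence[Span] = (),
                 protein_length: int = 0) -> Span:
    """Motif extension schedule.

    Levels 1-4 pad the minimal motif by cumulative +-n, +-2n, +-4n, +-6n
    residues where n is the motif length; level 5 spans from/to the
    neighbouring domain(s); level 6 is the full-length sequence.  Terminal
    motifs extend on one side only.  Results are clipped to [1, length].
    """
    if not (1 <= level <= 6):
        raise ValueError(f"motif extension level must be 1..6, got {level}")
    start, end = motif_span
    if protein_length < end or start < 1:
        raise ValueError(f"motif span {motif_span} outside [1, {protein_length}]")
    n = end - start + 1
    if level == 6:
        return (1, protein_length)
    if level == 5:
        lo, hi = start, end
        n_neigh = [d for d in neighbor_domains if d[1] < start]
        c_neigh = [d for d in neighbor_domains if d[0] > end]
        if n_neigh:
            lo = min(lo, max(n_neigh, key=lambda d: d[1])[0])
        if c_neigh:
            hi = max(hi, min(c_neigh, key=lambda d: d[0])[1])
        return _clip((lo, hi), protein_length)
    pad = {1: n, 2: 2 * n, 3: 4 * n, 4: 6 * n}[level]
    extend_n, extend_c = _one_sided(motif_span, protein_length)
    lo = start - pad if extend_n else start
    hi = end + pad if extend_c else end
    return _clip((lo, hi), protein_length)


def extend_domain(domain_span: Span, level: int,
                  neighbor_domains: Sequence[Span] = (),
                  protein_length: int = 0) -> Span:
    """Domain extension schedule.

    Level 1 grows through the flanking disordered regions up to the
    neighbouring domain boundaries (to the terminus when there is no
    neighbour); level 2 includes the neighbouring domains themselves; level 3
    is the full-length sequence.  Terminal domains extend on one side only.
    """
    if not (1 <= level <= 3):
        raise ValueError(f"domain extension level must be 1..3, got {level}")
    start, end = domain_span
    if protein_length < end or start < 1:
        raise ValueError(f"domain span {domain_span} outside [1, {protein_length}]")
    if level == 3:
        return (1, protein_length)
    n_neigh = [d for d in neighbor_domains if d[1] < start]
    c_neigh = [d for d in neighbor_domains if d[0] > end]
    nearest_n = max(n_neigh, key=lambda d: d[1]) if n_neigh else None
    nearest_c = min(c_neigh, key=lambda d: d[0]) if c_neigh else None
    extend_n, extend_c = _one_sided(domain_span, protein_length)
    if level == 1:
        lo = (nearest_n[1] + 1 if nearest_n else 1) if extend_n else start
        hi = (nearest_c[0] - 1 if nearest_c else protein_length) if extend_c else end
    else:  # level 2
        lo = (nearest_n[0] if nearest_n else 1) if extend_n else start
        hi = (nearest_c[1] if nearest_c else protein_length) if extend_c else end
    return _clip((min(lo, start), max(hi, end)), protein_length)


def minimal_extension_filter(previous_span: Span, new_span: Span) -> bool:
    """True = keep the extension step, False = drop it as minimal.

    A step is dropped when it adds fewer than 20 residues on the N side AND
    fewer than 20 on the C side relative to the previous step.
    """
    (ps, pe), (ns, ne) = previous_span, new_span
    if not (ns <= ps and ne >= pe):
        raise ValueError("new span must contain the previous span")
    added_n = ps - ns
    added_c = ne - pe
    return added_n >= MINIMAL_EXTENSION_RESIDUES or added_c >= MINIMAL_EXTENSION_RESIDUES
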