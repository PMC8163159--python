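"""Standard (Sprinzl) position numbering for mature tRNAs.

Every nucleotide of a mature tRNA receives a label from the standard tRNA
coordinate system (1..76, with D-loop insertions 17a/20a/20b and variable-arm
insertions e1..eN).  Labels make positions comparable across tRNAs of
different lengths: "58" is the T-loop adenosine whether the molecule is 74 or
92 nt long.

Numbering is obtained by global affine-gap alignment of the mature sequence
against a packaged cloverleaf consensus template.  The 3'-CCA is anchored to
labels 74-76 and, when the anticodon is known, its triplet is anchored to
34-36; the rest of the molecule is aligned freely.  Sequences whose best
alignment scores below a floor are flagged unfittable and keep raw
coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

# Consensus template: 76 columns labeled "1".."76".  The backbone string is a
# canonical cytosolic tRNA; columns listed in _CONSERVED carry near-invariant
# bases across the tRNA universe and are scored as strong matches, all other
# columns accept any base.
_BACKBONE = "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGAAGATCTGGAGGTCCTGTGTTCGATCCACAGAATTCGCACCA"
_CONSERVED = {8: "T", 14: "A", 18: "G", 19: "G", 21: "A", 33: "T",
              53: "G", 54: "T", 55: "T", 56: "C", 58: "A", 61: "C",
              74: "C", 75: "C", 76: "A"}
# dot-bracket cloverleaf over the 76 canonical columns
_STRUCTURE = (
    "(((((((..((((........)))).(((((.......))))).....(((((.......)))))))))))))..."
)

# canonical ordering key for labels: numeric part, then insertion suffix
_E_BASE = 45  # variable-arm insertions sort after column 45


class SprinzlError(ValueError):
    pass


@dataclass(frozen=True)
class SprinzlTemplate:
    """Alignment template: per-column labels, consensus weights, structure."""

    labels: tuple[str, ...]
    backbone: str
    conserved: dict[int, str]
    structure: str
    match: float = 2.0
    mismatch: float = -1.0
    neutral: float = 1.0  # any base at a non-conserved column
    backbone_bonus: float = 0.5  # weak preference for the consensus base
    gap_open: float = 5.0
    gap_extend: float = 1.0
    min_score: float = 20.0

    def column_score(self, col: int, base: str) -> float:
        """Score of placing ``base`` (A/C/G/T) on 1-based column ``col``.

        Non-conserved columns accept any base but weakly prefer the consensus
        one, which pins insertions to the column where the extra base sits
        rather than letting them drift through runs of equally scored columns.
        """
        want = self.conserved.get(col)
        if want is not None:
            return self.match if base == want else self.mismatch
        base_score = self.neutral
        if base == self.backbone[col - 1]:
            base_score += self.backbone_bonus
        return base_score


def default_template(domain: str = "cytosolic") -> SprinzlTemplate:
    """Packaged consensus template.

    The mitochondrial variant uses softer gap penalties: animal/amoebozoan
    mt-tRNAs often carry shortened D- or T-arms, which must not be punished
    into unfittability.
    """
    labels = tuple(str(i) for i in range(1, 77))
    if domain == "mitochondrial":
        return SprinzlTemplate(labels, _BACKBONE, dict(_CONSERVED), _STRUCTURE,
                               gap_open=3.0, gap_extend=0.5, min_score=10.0)
    return SprinzlTemplate(labels, _BACKBONE, dict(_CONSERVED), _STRUCTURE)


@dataclass(frozen=True)
class SprinzlMap:
    """Pairing of 1-based mature positions with Sprinzl labels."""

    cluster_id: str
    labels: tuple[tuple[int, str], ...]  # (mature_pos, label), ordered
    score: float = 0.0
    fit_ok: bool = True

    def label_of(self, pos: int) -> Optional[str]:
        for p, lab in self.labels:
            if p == pos:
                return lab
        return None

    def invert(self, label: str) -> Optional[int]:
        """Mature position carrying ``label``, or None when absent."""
        for p, lab in self.labels:
            if lab == label:
                return p
        return None

    def to_dict(self) -> dict[int, str]:
        return dict(self.labels)


def label_sort_key(label: str) -> tuple[float, str]:
    """Canonical ordering of Sprinzl labels ("20" < "20a" < "21", e-run after 45)."""
    if label.startswith("e"):
        return (_E_BASE + 0.5, f"{int(label[1:]):04d}")
    i = 0
    while i < len(label) and label[i].isdigit():
        i += 1
    num = int(label[:i])
    return (float(num), label[i:])


# ---------------------------------------------------------------------------
# alignment


def _affine_align(seq: str, cols: Sequence[int], template: SprinzlTemplate
                  ) -> tuple[float, list[tuple[Optional[int], Optional[int]]]]:
    """Global affine-gap alignment of ``seq`` to template columns ``cols``.

    Returns (score, path) where path pairs 0-based sequence indices with
    template column indices into ``cols`` (None = gap).  Traceback ties prefer
    diagonal (match) moves, then sequence insertions, giving deterministic
    leftmost gap placement.
    """
    cols = list(cols)
    n, m = len(seq), len(cols)
    NEG = float("-inf")
    go, ge = template.gap_open, template.gap_extend
    # M: seq i aligned to col j; X: gap in template (seq insertion); Y: gap in seq
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    # back-pointers: predecessor state for each cell/state
    bM = [[""] * (m + 1) for _ in range(n + 1)]
    bX = [[""] * (m + 1) for _ in range(n + 1)]
    bY = [[""] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -go - ge * (i - 1)
        bX[i][0] = "X" if i > 1 else "M"
    for j in range(1, m + 1):
        Y[0][j] = -go - ge * (j - 1)
        bY[0][j] = "Y" if j > 1 else "M"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = template.column_score(cols[j - 1], seq[i - 1])
            # diagonal move: tie-break prefers M predecessor, then X
            best, src = M[i - 1][j - 1], "M"
            if X[i - 1][j - 1] > best:
                best, src = X[i - 1][j - 1], "X"
            if Y[i - 1][j - 1] > best:
                best, src = Y[i - 1][j - 1], "Y"
            M[i][j] = best + s
            bM[i][j] = src
            best, src = M[i - 1][j] - go, "M"
            if X[i - 1][j] - ge > best:
                best, src = X[i - 1][j] - ge, "X"
            if Y[i - 1][j] - go > best:
                best, src = Y[i - 1][j] - go, "Y"
            X[i][j] = best
            bX[i][j] = src
            best, src = M[i][j - 1] - go, "M"
            if X[i][j - 1] - go > best:
                best, src = X[i][j - 1] - go, "X"
            if Y[i][j - 1] - ge > best:
                best, src = Y[i][j - 1] - ge, "Y"
            Y[i][j] = best
            bY[i][j] = src
    # final state: ties prefer M (match) over gap states
    state, score = "M", M[n][m]
    if X[n][m] > score:
        state, score = "X", X[n][m]
    if Y[n][m] > score:
        state, score = "Y", Y[n][m]
    i, j = n, m
    path: list[tuple[Optional[int], Optional[int]]] = []
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            state = bM[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            path.append((i - 1, None))
            state = bX[i][j]
            i -= 1
        else:
            path.append((None, j - 1))
            state = bY[i][j]
            j -= 1
    path.reverse()
    return score, path


def _insertion_labels(prev_label: Optional[str], count: int) -> list[str]:
    """Labels for ``count`` sequence insertions after template label ``prev_label``."""
    if prev_label is None:
        return [f"0{chr(ord('a') + k)}" for k in range(count)]
    if prev_label == "17":
        suffixes = ["a", "b", "c", "d"]
        return [f"17{suffixes[k]}" if k < 4 else f"17d{k - 3}" for k in range(count)]
    if prev_label == "20":
        out = []
        for k in range(count):
            if k == 0:
                out.append("20a")
            elif k == 1:
                out.append("20b")
            else:
                out.append(f"20b{k - 1}")
        return out
    if prev_label in {"44", "45", "46", "47"} or prev_label.startswith("e"):
        start = int(prev_label[1:]) if prev_label.startswith("e") else 0
        return [f"e{start + k + 1}" for k in range(count)]
    return [f"{prev_label}{chr(ord('a') + k)}" for k in range(count)]


def fit_to_template(
    mature_sequence: str,
    template: Optional[SprinzlTemplate] = None,
    cluster_id: str = "",
    anticodon: Optional[str] = None,
) -> SprinzlMap:
    """Assign Sprinzl labels to every position of a mature tRNA.

    The terminal CCA is anchored onto columns 74-76.  If ``anticodon`` is
    given and occurs near the middle of the molecule, its triplet is anchored
    onto columns 34-36 and the flanks are aligned independently.
    """
    template = template or default_template()
    seq = mature_sequence.upper()
    if not seq.endswith("CCA"):
        raise SprinzlError(f"{cluster_id or 'sequence'}: mature sequence must end in CCA")
    if not 60 <= len(seq) <= 120:
        raise SprinzlError(
            f"{cluster_id or 'sequence'}: length {len(seq)} outside [60, 120]"
        )
    body = seq[:-3]  # columns 1..73
    L = len(seq)

    anchor = _find_anticodon(body, anticodon) if anticodon else None
    if anchor is not None:
        s1, p1 = _affine_align(body[:anchor], range(1, 34), template)
        s2, p2 = _affine_align(body[anchor + 3 :], range(37, 74), template)
        score = s1 + s2 + 3 * template.match
        pairs = _pairs_from_path(p1, body_offset=0, cols=list(range(1, 34)))
        pairs += [(anchor + k, 34 + k) for k in range(3)]
        pairs += _pairs_from_path(p2, body_offset=anchor + 3, cols=list(range(37, 74)))
    else:
        score, path = _affine_align(body, range(1, 74), template)
        pairs = _pairs_from_path(path, body_offset=0, cols=list(range(1, 74)))

    labels: list[tuple[int, str]] = []
    prev_col_label: Optional[str] = None
    pending_insertions: list[int] = []
    for seq_i, col in pairs:
        if col is None:
            pending_insertions.append(seq_i)
            continue
        if pending_insertions:
            for k, ins_i in enumerate(
                _insertion_labels(prev_col_label, len(pending_insertions))
            ):
                labels.append((pending_insertions[k] + 1, ins_i))
            pending_insertions = []
        if seq_i is not None:
            labels.append((seq_i + 1, str(col)))
        prev_col_label = str(col)
    if pending_insertions:
        for k, lab in enumerate(_insertion_labels(prev_col_label, len(pending_insertions))):
            labels.append((pending_insertions[k] + 1, lab))

    labels += [(L - 2, "74"), (L - 1, "75"), (L, "76")]
    labels.sort(key=lambda pl: pl[0])
    fit_ok = score >= template.min_score
    return SprinzlMap(cluster_id=cluster_id, labels=tuple(labels),
                      score=score, fit_ok=fit_ok)


def _pairs_from_path(path, body_offset: int, cols: list[int]):
    out = []
    for si, cj in path:
        seq_i = None if si is None else si + body_offset
        col = None if cj is None else cols[cj]
        if seq_i is None and col is None:
            continue
        if seq_i is None:
            # template column deleted in this tRNA: no label emitted
            out.append((None, col))
        else:
            out.append((seq_i, col))
    return out


def _find_anticodon(body: str, anticodon: str) -> Optional[int]:
    """0-based index of the anticodon occurrence closest to column 34."""
    target = 33  # 0-based position of column 34 in a canonical tRNA
    hits = [i for i in range(len(body) - 2)
            if body[i : i + 3] == anticodon and abs(i - target) <= 8]
    if not hits:
        return None
    return min(hits, key=lambda i: abs(i - target))


def fit_clusters(clusters, template_nuc=None, template_mt=None) -> dict[str, SprinzlMap]:
    """Fit every cluster in a reference set; returns cluster_id -> SprinzlMap."""
    template_nuc = template_nuc or default_template("cytosolic")
    template_mt = template_mt or default_template("mitochondrial")
    out = {}
    for c in clusters:
        tpl = template_mt if c.origin == "mitochondrial" else template_nuc
        out[c.cluster_id] = fit_to_template(
            c.mature_sequence, tpl, cluster_id=c.cluster_id, anticodon=c.anticodon
        )
    return out


def write_sprinzl_tsv(maps: dict[str, SprinzlMap], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmature_pos\tsprinzl_label\n")
        for cid in sorted(maps):
            for pos, lab in maps[cid].labels:
                fh.write(f"{cid}\t{pos}\t{lab}\n")
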