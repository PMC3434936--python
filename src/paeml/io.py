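"""Readers and writers: delimited text and NEXUS matrices, Newick trees,
SIMMAP-style annotated Newick for sampled character histories.

NEXUS reading goes through dendropy (interleaved and non-interleaved
characters blocks both accepted); the emitted dialect is a minimal
``datatype=standard symbols="01"`` block that common phylogenetic
readers accept. Matrices are strictly binary: ``?`` or any other symbol outside
{0, 1} is a validation error naming the offending area and character, never
a third state.
"""

from __future__ import annotations

import io as _stdio
import os
import re

import dendropy
import numpy as np
import pandas as pd

from .matrix import MatrixValidationError, TaxonAreaMatrix
from .trees import AreaTree, FlatTree, TreeError


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# matrices


def _needs_quoting(name: str) -> bool:
    return bool(re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", name))


def _nexus_quote(name: str) -> str:
    if _needs_quoting(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def read_matrix(
    path: str | os.PathLike,
    format: str = "auto",
    *,
    transpose: bool = False,
) -> TaxonAreaMatrix:
    """Read a taxon-area matrix (areas x species).

    ``format`` is one of ``csv``, ``tsv``, ``nexus`` or ``auto`` (by file
    extension, falling back to a ``#NEXUS`` header sniff). Orientation is
    never guessed: a species x areas file needs ``transpose=True``.
    """
    path = os.fspath(path)
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        if ext in (".nex", ".nexus"):
            format = "nexus"
        elif ext == ".tsv":
            format = "tsv"
        elif ext == ".csv":
            format = "csv"
        else:
            with open(path) as fh:
                head = fh.read(6)
            format = "nexus" if head.upper().startswith("#NEXUS") else "csv"
    if format in ("csv", "tsv"):
        m = _read_delimited(path, "\t" if format == "tsv" else ",")
    elif format == "nexus":
        m = _read_nexus_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return m.transpose() if transpose else m


def _read_delimited(path: str, sep: str) -> TaxonAreaMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    areas = [str(a) for a in df.index]
    species = [str(s) for s in df.columns]
    try:
        cells = df.to_numpy(dtype=object)
        as_int = np.empty(cells.shape, dtype=np.int64)
        for (i, j), v in np.ndenumerate(cells):
            sv = str(v).strip()
            if sv not in ("0", "1"):
                raise MatrixValidationError(
                    f"{path}: non-binary state {sv!r} at area {areas[i]!r}, "
                    f"character {j} ({species[j]!r})"
                )
            as_int[i, j] = int(sv)
        return TaxonAreaMatrix(areas, species, as_int, provenance=path)
    except MatrixValidationError:
        raise


def _read_nexus_matrix(path: str) -> TaxonAreaMatrix:
    with open(path) as fh:
        text = fh.read()
    ntax, nchar = _nexus_dimensions(text)
    if nchar == 0:
        # dendropy rejects empty character blocks; taxa-only file
        labels = _nexus_taxa_labels(text, path)
        return TaxonAreaMatrix(
            labels, [], np.zeros((len(labels), 0), dtype=np.int8),
            provenance=path,
        )
    try:
        cm = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise ParseError(f"{path}: malformed NEXUS: {exc}") from exc
    areas, rows = [], []
    char_labels = None
    for taxon in cm.taxon_namespace:
        seq = cm[taxon]
        symbols = [str(s) for s in seq.symbols_as_list()]
        for j, sym in enumerate(symbols):
            if sym not in ("0", "1"):
                raise MatrixValidationError(
                    f"{path}: non-binary symbol {sym!r} at area "
                    f"{taxon.label!r}, character {j}"
                )
        areas.append(taxon.label)
        rows.append([int(s) for s in symbols])
    if cm.character_subsets or not char_labels:
        char_labels = _nexus_charlabels(text)
    ncol = len(rows[0]) if rows else 0
    if char_labels is None or len(char_labels) != ncol:
        char_labels = [f"char{j + 1}" for j in range(ncol)]
    return TaxonAreaMatrix(areas, char_labels, np.array(rows), provenance=path)


def _nexus_dimensions(text: str) -> tuple[int | None, int | None]:
    ntax = re.search(r"ntax\s*=\s*(\d+)", text, re.IGNORECASE)
    nchar = re.search(r"nchar\s*=\s*(\d+)", text, re.IGNORECASE)
    return (
        int(ntax.group(1)) if ntax else None,
        int(nchar.group(1)) if nchar else None,
    )


def _nexus_taxa_labels(text: str, path: str) -> list[str]:
    m = re.search(r"taxlabels\s+(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ParseError(f"{path}: no taxlabels block in zero-character file")
    labels = []
    for tok in re.findall(r"'(?:[^']|'')*'|\S+", m.group(1)):
        if tok.startswith("'"):
            tok = tok[1:-1].replace("''", "'")
        labels.append(tok)
    return labels


def _nexus_charlabels(text: str) -> list[str] | None:
    m = re.search(r"charlabels\s+(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not m:
        return None
    labels = []
    for tok in re.findall(r"'(?:[^']|'')*'|\S+", m.group(1)):
        if tok.startswith("'"):
            tok = tok[1:-1].replace("''", "'")
        labels.append(tok)
    return labels


def write_matrix(
    matrix: TaxonAreaMatrix, path: str | os.PathLike, format: str = "nexus"
) -> None:
    """Write a matrix as CSV (header row of species, first column of areas)
    or as a minimal NEXUS standard-data characters block."""
    path = os.fspath(path)
    if format == "csv":
        df = pd.DataFrame(
            matrix.cells, index=matrix.area_names, columns=matrix.species_names
        )
        df.to_csv(path, index_label="area")
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write(matrix_to_nexus(matrix))
    else:
        raise ValueError(f"unknown format {format!r}")


def matrix_to_nexus(matrix: TaxonAreaMatrix) -> str:
    buf = _stdio.StringIO()
    buf.write("#NEXUS\n\n")
    buf.write("begin taxa;\n")
    buf.write(f"    dimensions ntax={matrix.n_areas};\n")
    buf.write("    taxlabels\n")
    for a in matrix.area_names:
        buf.write(f"        {_nexus_quote(a)}\n")
    buf.write("    ;\nend;\n\n")
    buf.write("begin characters;\n")
    buf.write(f"    dimensions nchar={matrix.n_species};\n")
    buf.write('    format datatype=standard symbols="01" missing=? gap=-;\n')
    if matrix.n_species:
        buf.write("    charlabels\n")
        for s in matrix.species_names:
            buf.write(f"        {_nexus_quote(s)}\n")
        buf.write("    ;\n")
        buf.write("    matrix\n")
        width = max(len(_nexus_quote(a)) for a in matrix.area_names) + 2
        for i, a in enumerate(matrix.area_names):
            row = "".join(str(int(x)) for x in matrix.cells[i])
            buf.write(f"        {_nexus_quote(a):<{width}}{row}\n")
        buf.write("    ;\n")
    buf.write("end;\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# trees


def read_tree(source: str | os.PathLike) -> AreaTree:
    """Read a Newick tree from a path, or directly from a Newick string
    (detected by a ``(`` before any path separator)."""
    s = os.fspath(source)
    if "(" in s and not os.path.exists(s):
        return AreaTree.from_newick(s)
    with open(s) as fh:
        return AreaTree.from_newick(fh.read())


def write_tree(tree: AreaTree, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# SIMMAP-style annotated Newick
#
# Each branch carries its sampled state segments as {s1,d1:s2,d2:...} in
# parent-to-child order; durations sum to the branch length.

Segments = list[tuple[int, float]]


class SimmapError(ValueError):
    pass


def _check_segments(segs: Segments, length: float, where: str) -> None:
    if not segs:
        raise SimmapError(f"{where}: empty segment list on a branch")
    total = sum(d for _, d in segs)
    if abs(total - length) > 1e-9 * max(1.0, abs(length)):
        raise SimmapError(
            f"{where}: segment durations sum to {total}, branch length {length}"
        )
    for (s1, _), (s2, _) in zip(segs, segs[1:]):
        if s1 == s2:
            raise SimmapError(f"{where}: adjacent segments share state {s1}")


def write_simmap(
    flat: FlatTree,
    segments: dict[int, Segments],
    path: str | os.PathLike | None = None,
) -> str:
    """Serialise one sampled character history as SIMMAP-annotated Newick.

    ``segments`` maps each non-root node index to the (state, duration)
    segments of the branch above it, ordered parent to child. Returns the
    string; writes it to ``path`` when given.
    """
    for node in range(flat.n_nodes):
        if node == flat.root:
            continue
        segs = segments.get(node)
        if segs is None:
            raise SimmapError(f"no segments for branch above node {node}")
        _check_segments(segs, float(flat.lengths[node]), f"node {node}")

    def render(node: int) -> str:
        if node < flat.n_tips:
            core = _nexus_quote(flat.tip_names[node])
        else:
            core = "(" + ",".join(render(c) for c in flat.children[node]) + ")"
        if node == flat.root:
            return core
        ann = ":".join(f"{s},{d:.10g}" for s, d in segments[node])
        return core + ":{" + ann + "}"

    out = render(flat.root) + ";"
    if path is not None:
        with open(os.fspath(path), "w") as fh:
            fh.write(out + "\n")
    return out


_SIMMAP_BRANCH = re.compile(r"\{([^{}]*)\}")


def read_simmap(
    source: str | os.PathLike,
) -> tuple[AreaTree, dict[frozenset, Segments]]:
    """Parse a SIMMAP-annotated Newick string or file.

    Returns the tree (branch lengths = summed segment durations) and the
    segments per branch, keyed by the set of tip labels below that branch
    (a rooting-stable key usable for round-trip comparison).
    """
    s = os.fspath(source)
    if not ("(" in s and not os.path.exists(s)):
        with open(s) as fh:
            s = fh.read()
    s = s.strip()
    if not s.endswith(";"):
        raise SimmapError("missing terminal semicolon")

    segments_per_branch: list[Segments] = []

    def repl(m: re.Match) -> str:
        parts = m.group(1).split(":")
        segs: Segments = []
        for p in parts:
            try:
                st, dur = p.split(",")
                segs.append((int(st), float(dur)))
            except ValueError as exc:
                raise SimmapError(f"bad segment {p!r}") from exc
        segments_per_branch.append(segs)
        return f"[&seg={len(segments_per_branch) - 1}]:" + repr(
            sum(d for _, d in segs)
        )

    plain = _SIMMAP_BRANCH.sub(repl, s).replace(":[&", "[&")
    try:
        tree = dendropy.Tree.get(
            data=plain, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:
        raise SimmapError(f"could not parse SIMMAP newick: {exc}") from exc

    out: dict[frozenset, Segments] = {}
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        comments = [c for c in node.comments if c.startswith("&seg=")]
        if len(comments) != 1:
            raise SimmapError("branch without a segment annotation")
        idx = int(comments[0].split("=")[1])
        key = frozenset(lf.taxon.label for lf in node.leaf_iter())
        segs = segments_per_branch[idx]
        _check_segments(segs, node.edge.length, f"branch above {set(key)}")
        out[key] = segs
    return AreaTree(tree), out
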