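"""Reading and writing trees and character matrices (NEXUS / Newick).

Parsing is delegated to dendropy, which accepts both multistate dialects for
a taxon exhibiting both states of a binary character — Mesquite-style
``{01}`` and phylip-style ``(01)`` / ``(0 1)``; both are mapped to the
package's single POLYMORPHIC cell code.  ``?`` and ``-`` are both treated as
missing data.

On write, the CHARACTERS block is emitted by this module (Mesquite-style
``{01}`` tokens, CHARLABELS with the character names); trees are serialized
through dendropy's newick writer inside a TREES block.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import dendropy
import pandas as pd

from .characters import MISSING, POLYMORPHIC, STATE0, STATE1, CODE_SYMBOLS, CharacterMatrix


class NexusParseError(ValueError):
    pass


def _cell_code(state) -> int:
    """Map a dendropy StateIdentity to a cell code."""
    if state.symbol == "?":
        return MISSING
    syms = {f.symbol for f in state.fundamental_states} - {"-"}
    if state.symbol == "-" or not syms:
        return MISSING
    if syms == {"0"}:
        return STATE0
    if syms == {"1"}:
        return STATE1
    if syms == {"0", "1"}:
        # {} (uncertain) and () (polymorphic) dialects both mean "both states"
        return POLYMORPHIC
    raise NexusParseError(f"cell with states {sorted(syms)} is not binary")


# dendropy does not retain CHARLABELS, so recover character names directly.
_CHARLABELS_RE = re.compile(r"charlabels\s+(.*?);", re.IGNORECASE | re.DOTALL)


def _scan_charlabels(text: str) -> list[list[str]]:
    out = []
    for m in _CHARLABELS_RE.finditer(text):
        names = [tok.strip("'\"") for tok in m.group(1).split()]
        out.append(names)
    return out


def _convert_matrix(cm: dendropy.StandardCharacterMatrix, names: list[str] | None, label) -> CharacterMatrix:
    taxa = [t.label for t in cm.taxon_namespace if t in cm]
    nchar = max(len(cm[t]) for t in taxa) if taxa else 0
    if names is None or len(names) != nchar:
        names = [f"char{i + 1}" for i in range(nchar)]
    rows = {}
    for t in taxa:
        seq = cm[t]
        if len(seq) != nchar:
            raise NexusParseError(f"taxon {t!r}: {len(seq)} cells, expected {nchar}")
        rows[t] = [_cell_code(s) for s in seq]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    return CharacterMatrix(df, label=label)


def read_nexus(path) -> tuple[dendropy.Tree | None, list[CharacterMatrix]]:
    """Read a NEXUS file: (first tree or None, all character matrices in order)."""
    path = Path(path)
    text = path.read_text()
    try:
        ds = dendropy.DataSet.get(data=text, schema="nexus")
    except Exception as e:  # dendropy raises several error types with line info
        raise NexusParseError(f"{path}: {e}") from e
    tree = None
    for tl in ds.tree_lists:
        if len(tl):
            tree = tl[0]
            tree.is_rooted = True
            break
    labelsets = _scan_charlabels(text)
    matrices = []
    for i, cm in enumerate(ds.char_matrices):
        names = labelsets[i] if i < len(labelsets) else None
        matrices.append(_convert_matrix(cm, names, cm.label))
    return tree, matrices


def read_newick(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=False)


def _quote(label: str) -> str:
    if re.search(r"[\s(){}\[\]/\\,;:=*'\"`<>+-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _characters_block(matrix: CharacterMatrix) -> str:
    lines = [
        "BEGIN CHARACTERS;",
        f"\tTITLE {_quote(matrix.label)};" if matrix.label else None,
        f"\tDIMENSIONS NCHAR={len(matrix.characters)};",
        '\tFORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "\tCHARLABELS " + " ".join(_quote(c) for c in matrix.characters) + ";",
        "\tMATRIX",
    ]
    df = matrix.data
    width = max(len(_quote(t)) for t in matrix.taxa) + 2
    for taxon in matrix.taxa:
        cells = "".join(CODE_SYMBOLS[int(v)] for v in df.loc[taxon])
        lines.append(f"\t{_quote(taxon):<{width}}{cells}")
    lines += ["\t;", "END;"]
    return "\n".join(l for l in lines if l is not None)


def write_nexus(
    path,
    tree: dendropy.Tree | None = None,
    matrices: Sequence[CharacterMatrix] = (),
) -> None:
    """Write a NEXUS file with TAXA, CHARACTERS and TREES blocks."""
    if tree is None and not matrices:
        raise ValueError("nothing to write")
    if matrices:
        taxa = matrices[0].taxa
    else:
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    blocks = ["#NEXUS", ""]
    blocks.append(
        "BEGIN TAXA;\n\tDIMENSIONS NTAX={};\n\tTAXLABELS\n\t\t{}\n\t;\nEND;".format(
            len(taxa), "\n\t\t".join(_quote(t) for t in taxa)
        )
    )
    for m in matrices:
        blocks.append(_characters_block(m))
    if tree is not None:
        newick = tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=False
        ).strip()
        blocks.append(f"BEGIN TREES;\n\tTREE tree1 = [&R] {newick}\nEND;")
    Path(path).write_text("\n\n".join(blocks) + "\n")
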