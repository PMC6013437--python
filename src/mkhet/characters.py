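"""Binary character matrices over the four-symbol alphabet {0, 1, ?, {01}}.

Each cell of a matrix is one of four codes: the two determinate states,
missing data, or a polymorphic observation (the taxon exhibits both states).
For likelihood and parsimony purposes missing and polymorphic cells both
license the full state set {0, 1}; they differ only for rescoring, which
replaces polymorphic cells by a presumed derived state while leaving missing
cells untouched.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Cell codes. Kept as plain ints so matrices pack into int8 arrays.
STATE0 = 0
STATE1 = 1
MISSING = 2
POLYMORPHIC = 3

_VALID_CODES = frozenset({STATE0, STATE1, MISSING, POLYMORPHIC})

#: NEXUS rendering of each code (Mesquite-style polymorphism token).
CODE_SYMBOLS = {STATE0: "0", STATE1: "1", MISSING: "?", POLYMORPHIC: "{01}"}

#: Allowed fundamental states per code, used by likelihood and parsimony.
ALLOWED_STATES = {
    STATE0: (0,),
    STATE1: (1,),
    MISSING: (0, 1),
    POLYMORPHIC: (0, 1),
}


class CharacterMatrix:
    """An ordered taxa x characters table of binary-character cells.

    Parameters
    ----------
    data:
        DataFrame indexed by taxon label with one column per character;
        values must be the integer cell codes (``STATE0``, ``STATE1``,
        ``MISSING``, ``POLYMORPHIC``).
    label:
        Optional name for the matrix (e.g. "rescored" vs "original").
    """

    def __init__(self, data: pd.DataFrame, label: str | None = None):
        arr = data.to_numpy()
        bad = set(np.unique(arr)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid cell codes {sorted(bad)}; expected one of {sorted(_VALID_CODES)}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon labels: {dups}")
        self._data = data.astype(np.int8)
        self.label = label

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(
        cls,
        cells: Mapping[str, Iterable[int]],
        characters: Iterable[str],
        label: str | None = None,
    ) -> "CharacterMatrix":
        """Build from {taxon: [codes...]} preserving insertion order."""
        df = pd.DataFrame.from_dict(dict(cells), orient="index", columns=list(characters))
        return cls(df, label=label)

    @property
    def taxa(self) -> list[str]:
        return list(self._data.index)

    @property
    def characters(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def data(self) -> pd.DataFrame:
        """The underlying int8 DataFrame (a copy; the matrix is immutable)."""
        return self._data.copy()

    def column(self, character: str) -> dict[str, int]:
        """Cells of one character as {taxon: code}."""
        if character not in self._data.columns:
            raise KeyError(f"character {character!r} not in matrix")
        return self._data[character].to_dict()

    def cell(self, taxon: str, character: str) -> int:
        return int(self._data.at[taxon, character])

    def to_symbols(self) -> pd.DataFrame:
        """Human/NEXUS-readable view ('0', '1', '?', '{01}')."""
        return self._data.replace(CODE_SYMBOLS)

    def __eq__(self, other) -> bool:  # cells, taxa and characters, in order
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<CharacterMatrix{lab}: {self.shape[0]} taxa x {self.shape[1]} characters>"


def rescore_polymorphic(
    matrix: CharacterMatrix, derived_map: Mapping[str, int]
) -> tuple[CharacterMatrix, dict[str, int]]:
    """Replace every polymorphic cell by the presumed derived state.

    A taxon scored as exhibiting both states of a character is assumed to be
    fixing the derived state, so the cell is recoded to it; missing and
    determinate cells are untouched.  Returns the rescored matrix and, per
    character, the number of taxa whose cell changed.

    ``derived_map`` must name the derived state (0 or 1) for every character
    in the matrix.
    """
    missing_chars = [c for c in matrix.characters if c not in derived_map]
    if missing_chars:
        raise KeyError(f"derived state not specified for characters: {missing_chars}")
    for c, s in derived_map.items():
        if s not in (STATE0, STATE1):
            raise ValueError(f"derived state for {c!r} must be 0 or 1, got {s!r}")
    df = matrix.data
    counts: dict[str, int] = {}
    for c in matrix.characters:
        mask = df[c] == POLYMORPHIC
        counts[c] = int(mask.sum())
        df.loc[mask, c] = derived_map[c]
    return CharacterMatrix(df, label=matrix.label), counts
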