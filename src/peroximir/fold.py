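"""RNA secondary-structure folding behind a single pluggable contract.

A folding engine is any callable ``fold(seq) -> (structure, mfe)`` that,
given a sequence (DNA or RNA alphabet), deterministically returns a
nested dot-bracket string of equal length and the minimum free energy in
kcal/mol. The default engine wraps the ViennaRNA thermodynamic folder
(default parameters), the standard choice for plant pre-miRNA hairpin
prediction.
"""

from __future__ import annotations

from typing import Callable, Tuple

from .sequtil import to_rna

FoldEngine = Callable[[str], Tuple[str, float]]


def viennarna_fold(seq: str) -> Tuple[str, float]:
    """Fold with ViennaRNA (RNAfold defaults): dot-bracket + MFE (kcal/mol)."""
    import RNA

    structure, mfe = RNA.fold(to_rna(seq))
    return structure, float(mfe)


def default_engine() -> FoldEngine:
    return viennarna_fold


def pair_table(structure: str) -> list[int]:
    """Partner index for each position of a dot-bracket string (-1 = unpaired).

    Raises ``ValueError`` on unbalanced structures, which would violate
    the folding-engine contract.
    """
    stack: list[int] = []
    table = [-1] * len(structure)
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {i}")
            j = stack.pop()
            table[i] = j
            table[j] = i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced structure: {len(stack)} unclosed pairs")
    return table
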