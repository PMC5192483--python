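"""Nearest-neighbor free-energy model for RNA:RNA heteroduplexes.

Stacking free energies (ΔG°37, kcal/mol) follow the Turner-style
nearest-neighbor scheme: a duplex contributes one initiation penalty,
one stacking term per step of two adjacent base pairs, and a terminal
penalty for every helix end closed by an A:U or G:U pair.  Watson-Crick
stack values are the Xia et al. set; wobble-containing stacks use
Turner-style values for G:U steps.  Unpaired positions interrupt
stacking, so an interior loop or bulge simply splits the duplex into
independent helices that share the single initiation term.

A step is keyed ``(a, b, c, d)`` for ``5'-a b-3'`` over ``3'-c d-5'``
with pairs a:c and b:d (encoded bases, see :mod:`cerna_screen.seq`).
Reversal symmetry (reading the duplex from the other strand) maps
``(a, b, c, d)`` to ``(d, c, b, a)``; the table stores one orientation
and mirrors the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq import A, C, G, U, encode, is_paired

_WC_STACKS = {
    (A, A, U, U): -0.93,
    (A, U, U, A): -1.10,
    (U, A, A, U): -1.33,
    (C, U, G, A): -2.08,
    (C, A, G, U): -2.11,
    (G, U, C, A): -2.24,
    (G, A, C, U): -2.35,
    (C, G, G, C): -2.36,
    (G, G, C, C): -3.26,
    (G, C, C, G): -3.42,
}

_GU_STACKS = {
    (A, G, U, U): -0.55,
    (A, U, U, G): -1.36,
    (C, G, G, U): -1.41,
    (C, U, G, G): -2.11,
    (G, G, C, U): -1.53,
    (G, U, C, G): -2.51,
    (U, G, A, U): -1.27,
    (U, U, A, G): -1.00,
    (G, G, U, U): -0.50,
    (G, U, U, G): +0.47,
    (U, G, G, U): -0.57,
}

DUPLEX_INITIATION = 4.09
TERMINAL_AU_PENALTY = 0.45  # per helix end closed by an A:U or G:U pair


def _full_stack_table() -> dict[tuple[int, int, int, int], float]:
    table: dict[tuple[int, int, int, int], float] = {}
    for src in (_WC_STACKS, _GU_STACKS):
        for (a, b, c, d), v in src.items():
            table[(a, b, c, d)] = v
            table[(d, c, b, a)] = v
    return table


@dataclass(frozen=True)
class NearestNeighborTable:
    """Stack/initiation/terminal parameters for duplex ΔG evaluation."""

    stacks: dict = field(default_factory=_full_stack_table)
    initiation: float = DUPLEX_INITIATION
    terminal_au: float = TERMINAL_AU_PENALTY

    def stack(self, a: int, b: int, c: int, d: int) -> float:
        """ΔG of the step 5'-ab-3' / 3'-cd-5' (pairs a:c, b:d)."""
        return self.stacks[(a, b, c, d)]

    def terminal(self, a: int, c: int) -> float:
        """Penalty for a helix terminated by the pair a:c."""
        return 0.0 if a + c == 3 and (a in (C, G)) else self.terminal_au


DEFAULT_NN = NearestNeighborTable()


def helix_pairs_energy(pairs: list[tuple[int, int, bool]],
                       nn: NearestNeighborTable = DEFAULT_NN) -> float:
    """ΔG of a pairing map: ``pairs[k] = (top_base, bottom_base, paired)``
    ordered 5'→3' along the top strand; unpaired entries break stacking.

    Includes one initiation term regardless of helix count.
    """
    dg = nn.initiation
    run: list[tuple[int, int]] = []
    runs: list[list[tuple[int, int]]] = []
    for a, c, p in pairs:
        if p:
            run.append((a, c))
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)
    for r in runs:
        dg += nn.terminal(*r[0]) + nn.terminal(*r[-1])
        for (a, c), (b, d) in zip(r[:-1], r[1:]):
            dg += nn.stack(a, b, c, d)
    return dg


def duplex_energy_strings(top: str, bottom: str,
                          nn: NearestNeighborTable = DEFAULT_NN) -> float:
    """Convenience: ΔG of two aligned strands (top 5'→3', bottom 3'→5')."""
    t, b = encode(top), encode(bottom)
    if len(t) != len(b):
        raise ValueError("strands must have equal aligned length")
    pairs = [(int(x), int(y), is_paired(int(x), int(y))) for x, y in zip(t, b)]
    return helix_pairs_energy(pairs, nn)
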