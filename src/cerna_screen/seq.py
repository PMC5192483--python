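"""Low-level RNA sequence utilities.

Sequences are handled internally as ``uint8`` arrays with the encoding
A=0, C=1, G=2, U=3.  Under this encoding two bases ``x`` and ``y`` form a
Watson-Crick pair iff ``x + y == 3`` (A:U, C:G) and a G:U wobble pair iff
``x + y == 5``.  This makes vectorised pairing tests a single addition.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGU"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["T"] = _CODE["U"]

A, C, G, U = 0, 1, 2, 3


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a non-nucleotide character."""


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string (case-insensitive, T -> U) as uint8 codes."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = _CODE[ch]
        except KeyError:
            raise SequenceAlphabetError(
                f"non-nucleotide character {ch!r} at position {i + 1}"
            ) from None
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Watson-Crick reverse complement (A<->U, C<->G) of an encoded array."""
    return (3 - codes[::-1]).astype(np.uint8)


def is_wc(x: int, y: int) -> bool:
    return x + y == 3


def is_gu(x: int, y: int) -> bool:
    return x + y == 5


def is_paired(x: int, y: int) -> bool:
    s = x + y
    return s == 3 or s == 5


def random_background(length: int, rng: np.random.Generator,
                      composition=(0.3, 0.2, 0.2, 0.3)) -> np.ndarray:
    """Random transcript background with a fixed A/C/G/U composition.

    The default composition is mildly AU-rich, as is typical of lncRNA
    exons.  Sampling is i.i.d., so the dinucleotide frequencies equal the
    products of mononucleotide frequencies — exactly the family preserved
    by the dinucleotide shuffle used for empirical site p-values.
    """
    return rng.choice(4, size=length, p=np.asarray(composition)).astype(np.uint8)


def dinucleotide_shuffle(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erickson style: the sequence is viewed as an Eulerian walk on
    the multigraph whose edges are its dinucleotides.  For every vertex
    other than the terminal character a random outgoing "last edge" is
    drawn until the chosen last-edge graph connects every vertex to the
    terminal one; the remaining out-edges are then permuted uniformly and
    the walk is replayed from the original first character.  First and
    last characters, mono- and dinucleotide counts are all invariant.
    """
    n = len(codes)
    if n <= 2:
        return codes.copy()
    first, last = int(codes[0]), int(codes[-1])
    # out-edge multisets
    out: dict[int, list[int]] = {}
    for a, b in zip(codes[:-1], codes[1:]):
        out.setdefault(int(a), []).append(int(b))
    vertices = list(out.keys())
    for b in codes[1:]:
        if int(b) not in out:
            out.setdefault(int(b), [])
            vertices.append(int(b))

    nonterminal = [v for v in vertices if v != last and out[v]]
    while True:
        last_edge = {v: out[v][rng.integers(len(out[v]))] for v in nonterminal}
        # every nonterminal vertex must reach `last` through last-edges
        ok = True
        for v in nonterminal:
            seen = set()
            w = v
            while w != last and w in last_edge and w not in seen:
                seen.add(w)
                w = last_edge[w]
            if w != last:
                ok = False
                break
        if ok:
            break

    shuffled_out: dict[int, list[int]] = {}
    for v in vertices:
        edges = list(out[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        rng.shuffle(edges)
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled_out[v] = edges

    result = np.empty(n, dtype=np.uint8)
    result[0] = first
    ptr = {v: 0 for v in vertices}
    w = first
    for i in range(1, n):
        nxt = shuffled_out[w][ptr[w]]
        ptr[w] += 1
        result[i] = nxt
        w = nxt
    return result
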