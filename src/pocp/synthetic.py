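"""Synthetic proteome pairs with a controlled shared-protein fraction.

Residues are drawn i.i.d. from the BLOSUM62 background amino-acid
frequencies, which keeps chance identity between unrelated proteins low and
stable — random protein pairs essentially never exceed 40% identity over
more than half their length, so the expected POCP of an unrelated pair is
near zero and the expected POCP of a pair sharing a fraction f of its
proteins is 100*f. Shared proteins carry different ids in the two
proteomes, so conservation must be detected by alignment, never by id
matching. Point mutations (substitutions to a uniformly random different
residue; no indels) let tests push shared proteins toward and past the 40%
identity filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fasta_io import Proteome, ProteinRecord

#: BLOSUM62 background amino-acid frequencies (canonical 20 residues).
BLOSUM62_BACKGROUND = {
    "A": 0.0742, "R": 0.0520, "N": 0.0446, "D": 0.0536, "C": 0.0247,
    "Q": 0.0346, "E": 0.0543, "G": 0.0742, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0221, "F": 0.0473, "P": 0.0391,
    "S": 0.0572, "T": 0.0509, "W": 0.0131, "Y": 0.0321, "V": 0.0729,
}

_RESIDUES = np.array(list(BLOSUM62_BACKGROUND), dtype="U1")
_FREQS = np.array(list(BLOSUM62_BACKGROUND.values()))
_FREQS = _FREQS / _FREQS.sum()


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Recipe for one proteome pair with a known shared fraction."""

    n_proteins: int
    shared_fraction: float
    length_range: tuple[int, int] = (100, 400)
    point_mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if not (0.0 <= self.point_mutation_rate < 1.0):
            raise ValueError("point_mutation_rate must be in [0, 1)")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length_range must satisfy 30 <= lo <= hi")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=_FREQS))


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    arr = np.array(list(sequence), dtype="U1")
    mask = rng.random(arr.size) < rate
    for i in np.flatnonzero(mask):
        choices = _RESIDUES[_RESIDUES != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def generate_proteome(
    n: int,
    length_range: tuple[int, int] = (100, 400),
    seed: int = 0,
    label: str = "synthetic",
) -> Proteome:
    """*n* proteins with i.i.d. background-frequency residues; deterministic
    under *seed*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 30 or hi < lo:
        raise ValueError("length_range must satisfy 30 <= lo <= hi")
    rng = np.random.default_rng(seed)
    records = [
        ProteinRecord(
            id=f"{label}_{i + 1:05d}",
            sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
        )
        for i in range(n)
    ]
    return Proteome(label=label, records=records)


def generate_pair(spec: SyntheticPairSpec) -> tuple[Proteome, Proteome, float]:
    """Two proteomes sharing exactly round(n * f) proteins.

    Returns (proteome_a, proteome_b, expected_pocp_pct) with
    expected_pocp_pct = 100 * (2k)/(2n) = 100 * k/n by construction (shared
    copies are identical when point_mutation_rate is 0). Shared proteins sit
    at random positions and carry proteome-specific ids.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    k = round(n * spec.shared_fraction)
    lo, hi = spec.length_range

    shared = [_random_sequence(rng, int(rng.integers(lo, hi + 1))) for _ in range(k)]
    unique_a = [_random_sequence(rng, int(rng.integers(lo, hi + 1))) for _ in range(n - k)]
    unique_b = [_random_sequence(rng, int(rng.integers(lo, hi + 1))) for _ in range(n - k)]
    shared_b = [_mutate(rng, s, spec.point_mutation_rate) for s in shared]

    seqs_a = shared + unique_a
    seqs_b = shared_b + unique_b
    order_a = rng.permutation(n)
    order_b = rng.permutation(n)

    prot_a = Proteome(
        label="synthA",
        records=[
            ProteinRecord(id=f"a_{i + 1:05d}", sequence=seqs_a[order_a[i]])
            for i in range(n)
        ],
    )
    prot_b = Proteome(
        label="synthB",
        records=[
            ProteinRecord(id=f"b_{i + 1:05d}", sequence=seqs_b[order_b[i]])
            for i in range(n)
        ],
    )
    return prot_a, prot_b, 100.0 * k / n
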