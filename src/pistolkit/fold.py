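"""Equilibrium secondary-structure ensemble for accessibility scoring.

A target region is folded with a McCaskill-style partition function over
*nested* secondary structures (no pseudoknots) built from Watson-Crick and
GU wobble pairs, under a deliberately simple energy model: each pair type
carries a fixed stacking-free formation energy, hairpin loops must span at
least ``min_hairpin`` unpaired bases, and loops are otherwise free.  That
is all that is needed to rank cleavage sites by how unpaired they are in
the Boltzmann ensemble, and it keeps the model fully checkable against
exhaustive structure enumeration on short sequences.

The inside recursion over an interval ``[i, j]`` is

    Z(i, j) = Z(i+1, j) + sum_k  w(i, k) * Z(i+1, k-1) * Z(k+1, j)

with ``w(i, k) = exp(-dG(pair)/RT)`` for admissible pairs, and base-pair
probabilities come from the matching outside (inside-outside) recursion.
All arithmetic is carried in log space, so partition functions stay finite
for windows of several hundred nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnergyModel", "FoldResult", "partition_fold", "GAS_CONSTANT_KCAL"]

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)


def _lse(v: np.ndarray) -> float:
    """log-sum-exp of a 1-D array; -inf for an empty or all--inf input."""
    if v.size == 0:
        return -np.inf
    m = v.max()
    if not np.isfinite(m):
        return m
    return m + np.log(np.exp(v - m).sum())

_DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -3.0,
    ("A", "U"): -2.0,
    ("G", "U"): -1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Per-pair free energies (kcal/mol), minimum hairpin span, temperature.

    ``pair_energies`` maps unordered base pairs to formation free energies;
    anything not listed (including masked ``N`` bases) cannot pair.
    """

    pair_energies: tuple = tuple(sorted(_DEFAULT_PAIR_ENERGIES.items()))
    min_hairpin: int = 3
    temperature_c: float = 37.0

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KCAL * (self.temperature_c + 273.15)

    def pair_table(self) -> dict[tuple[str, str], float]:
        table: dict[tuple[str, str], float] = {}
        for (a, b), e in self.pair_energies:
            table[(a, b)] = e
            table[(b, a)] = e
        return table

    def log_weight_matrix(self, seq: str) -> np.ndarray:
        """log w(i, j) for every admissible pair; -inf elsewhere."""
        n = len(seq)
        table = self.pair_table()
        w = np.full((n, n), -np.inf)
        for i in range(n):
            for j in range(i + self.min_hairpin + 1, n):
                e = table.get((seq[i], seq[j]))
                if e is not None:
                    w[i, j] = -e / self.rt
        return w


@dataclass
class FoldResult:
    """Ensemble quantities for one folded sequence window.

    ``pair_probability`` is the symmetric matrix P(i, j) of equilibrium
    pairing probabilities over window positions (0-based within window);
    ``unpaired_probability`` is q(i) = 1 - sum_j P(i, j); the partition
    function is reported in log space and exponentiated on demand.
    """

    sequence: str
    log_partition: float
    pair_probability: np.ndarray
    unpaired_probability: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        q = 1.0 - self.pair_probability.sum(axis=1)
        self.unpaired_probability = np.clip(q, 0.0, 1.0)

    @property
    def partition_function(self) -> float:
        return float(np.exp(self.log_partition))

    def mfe_like_structure(self, threshold: float = 0.5) -> str:
        """Dot-bracket of pairs with P > threshold (a representative, not an MFE).

        With threshold >= 0.5 the selected pairs can neither conflict nor
        cross, because two mutually exclusive pairs cannot both exceed
        probability one half.
        """
        n = len(self.sequence)
        chars = ["."] * n
        for i in range(n):
            for j in range(i + 1, n):
                if self.pair_probability[i, j] > threshold:
                    chars[i], chars[j] = "(", ")"
        return "".join(chars)


def partition_fold(seq: str, model: EnergyModel | None = None) -> FoldResult:
    """Inside-outside partition function over nested structures.

    Returns finite log-domain results for any window length; a sequence too
    short to form a hairpin yields the open chain only (Z = 1, q = 1).
    """
    model = model or EnergyModel()
    n = len(seq)
    h = model.min_hairpin
    if n == 0:
        return FoldResult(seq, 0.0, np.zeros((0, 0)))
    if n < h + 2:
        return FoldResult(seq, 0.0, np.zeros((n, n)))

    w = model.log_weight_matrix(seq)

    # Inside. A[i, j+1] = log Z(i, j); empty intervals (j < i) are log 1 = 0.
    A = np.full((n + 2, n + 2), -np.inf)
    for i in range(n + 2):
        A[i, : i + 1] = 0.0
    for span in range(n):
        for i in range(n - span):
            j = i + span
            best = A[i + 1, j + 1]
            k0 = i + h + 1
            if k0 <= j:
                v = w[i, k0 : j + 1] + A[i + 1, k0 : j + 1] + A[k0 + 1 : j + 2, j + 1]
                s = _lse(v)
                if np.isfinite(s):
                    best = np.logaddexp(best, s)
            A[i, j + 1] = best
    log_z = A[0, n]

    # log Zb(i, k) = log w(i, k) + log Z(i+1, k-1)
    lzb = w + A[1 : n + 1, 0:n]

    # Outside over interval nonterminals S(i, j); B[i, j+1] = log out(i, j).
    B = np.full((n + 1, n + 1), -np.inf)
    B[0, n] = 0.0
    for i in range(n):
        for j in range(n - 1, i - 1, -1):
            if i == 0 and j == n - 1:
                continue
            terms = []
            if i >= 1:
                terms.append(B[i - 1, j + 1])  # parent consumed one unpaired base
                # parent S(m, j) placed pair (m, i-1) to our left
                if i >= 2:
                    s = _lse(B[0 : i - 1, j + 1] + lzb[0 : i - 1, i - 1])
                    if np.isfinite(s):
                        terms.append(s)
                # we are the interior of pair (i-1, j+1)
                if j + 1 <= n - 1 and np.isfinite(w[i - 1, j + 1]):
                    s = _lse(B[i - 1, j + 2 : n + 1] + A[j + 2, j + 2 : n + 1])
                    if np.isfinite(s):
                        terms.append(w[i - 1, j + 1] + s)
            if terms:
                B[i, j + 1] = _lse(np.array(terms))

    # P(i, k) = Zb(i, k) * sum_l out(i, l) Z(k+1, l) / Z
    prob = np.zeros((n, n))
    for i in range(n):
        for k in range(i + h + 1, n):
            if not np.isfinite(lzb[i, k]):
                continue
            s = _lse(B[i, k + 1 : n + 1] + A[k + 1, k + 1 : n + 1])
            if not np.isfinite(s):
                continue
            p = np.exp(lzb[i, k] + s - log_z)
            prob[i, k] = prob[k, i] = min(p, 1.0)

    return FoldResult(seq, float(log_z), prob)
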