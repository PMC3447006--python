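"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own algorithms: inbreeding is
cross-checked against a recursive-kinship computation and a Monte-Carlo
gene-dropping simulation, and tetrasomic gamete draws against the exact
enumerated distribution.
"""

from __future__ import annotations

import numpy as np

from ploidysel.pedigree import Pedigree


def _topological_ids(ped: Pedigree) -> list[str]:
    """Pedigree ids ordered parents-before-children."""
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(i: str) -> None:
        if state.get(i):
            return
        state[i] = 1
        for p in ped.record(i).known_parents():
            visit(p)
        order.append(i)

    for rec in ped:
        visit(rec.id)
    return order


def kinship_inbreeding(ped: Pedigree) -> dict[str, float]:
    """Exact inbreeding coefficients via the recursive kinship (coancestry)
    matrix, assuming disomic transmission: F_X = f(dam_X, sire_X), with
    f(i,i) = (1 + F_i)/2 and f(i,j) = (f(dam_i, j) + f(sire_i, j))/2 for i
    added after j.  Unknown parents contribute zero kinship."""
    order = _topological_ids(ped)
    index = {i: k for k, i in enumerate(order)}
    n = len(order)
    f = np.zeros((n, n))
    for k, i in enumerate(order):
        rec = ped.record(i)
        parents = [index[p] for p in rec.known_parents()]
        if len(parents) == 2:
            f_self = 0.5 * (1.0 + f[parents[0], parents[1]])
        else:
            f_self = 0.5
        f[k, k] = f_self
        for j in range(k):
            val = sum(f[p, j] for p in parents) / 2.0
            f[k, j] = f[j, k] = val
    out: dict[str, float] = {}
    for i in order:
        rec = ped.record(i)
        parents = rec.known_parents()
        if len(parents) == 2:
            out[i] = float(f[index[parents[0]], index[parents[1]]])
        else:
            out[i] = 0.0
    return out


def gene_drop_inbreeding(
    ped: Pedigree, ids: list[str], n_reps: int, seed: int
) -> dict[str, float]:
    """Monte-Carlo gene dropping (disomic): founders get unique allele
    labels, every individual inherits one random allele from each parent
    (unknown parents contribute fresh unique alleles), and F is the fraction
    of replicates in which the two alleles are identical by descent."""
    rng = np.random.default_rng(seed)
    order = _topological_ids(ped)
    index = {i: k for k, i in enumerate(order)}
    n = len(order)
    hits = {i: 0 for i in ids}
    for _ in range(n_reps):
        alleles = np.empty((n, 2), dtype=np.int64)
        fresh = 0
        for k, i in enumerate(order):
            rec = ped.record(i)
            for slot, parent in enumerate((rec.dam_id, rec.sire_id)):
                if parent in index:
                    pick = int(rng.integers(2))
                    alleles[k, slot] = alleles[index[parent], pick]
                else:
                    alleles[k, slot] = fresh
                    fresh += 1
        for i in ids:
            k = index[i]
            if alleles[k, 0] == alleles[k, 1]:
                hits[i] += 1
    return {i: hits[i] / n_reps for i in ids}


def tetrasomic_gamete_pmf(dosage: int, alpha: float = 0.0) -> np.ndarray:
    """Exact P(gamete focal-allele count = 0, 1, 2) for a tetraploid parent
    with the given per-locus dosage.

    Random chromosome segregation draws 2 of the 4 alleles without
    replacement (hypergeometric); with probability ``alpha`` the gamete
    instead carries two copies of one uniformly chosen parental allele.
    """
    from math import comb

    d = dosage
    hyper = np.array(
        [comb(d, g) * comb(4 - d, 2 - g) / comb(4, 2) for g in range(3)],
        dtype=float,
    )
    dr = np.array([1.0 - d / 4.0, 0.0, d / 4.0])
    return (1.0 - alpha) * hyper + alpha * dr
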