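"""Generalized four-gamete compatibility test for unphased genotypes of any ploidy.

Two polarized biallelic sites are incompatible with a single genealogy when all
three derived two-site haplotypes (01, 10, 11) must exist.  With unphased
derived-allele counts this can be decided per individual: count ``a`` at the
first site and ``b`` at the second, with ploidy ``k``, prove

* ``10`` present whenever ``a > b``,
* ``01`` present whenever ``b > a``,
* ``11`` present whenever ``a + b > k``.

The test is exact for haploids and makes a maximum-parsimony assumption for
higher ploidies: some genuinely incompatible pairs are passed (e.g. genotypes
12 and 11 across two diploids), so joint conflicts are left to tree building.
"""

from __future__ import annotations

import numpy as np

__all__ = ["incompatible", "haplotype_certificates"]


def incompatible(p, q, ploidies) -> bool:
    """Return True iff site patterns ``p`` and ``q`` cannot share one genealogy.

    Parameters
    ----------
    p, q
        Integer vectors of derived-allele counts per individual.
    ploidies
        Per-individual ploidy vector of the same length.
    """
    p = np.asarray(p)
    q = np.asarray(q)
    k = np.asarray(ploidies)
    if p.shape != q.shape or p.shape != k.shape:
        raise ValueError(
            f"pattern/ploidy length mismatch: {p.shape}, {q.shape}, {k.shape}"
        )
    return bool(np.any(p > q) and np.any(q > p) and np.any(p + q > k))


def haplotype_certificates(p, q, ploidies) -> set[str]:
    """Derived two-site haplotypes provably present given the two count patterns.

    Returns a subset of ``{"01", "10", "11"}`` (the ancestral ``00`` is assumed
    to exist for polarized data and never reported).  ``incompatible(p, q, k)``
    is exactly "all three certificates present".
    """
    p = np.asarray(p)
    q = np.asarray(q)
    k = np.asarray(ploidies)
    if p.shape != q.shape or p.shape != k.shape:
        raise ValueError("pattern/ploidy length mismatch")
    certs: set[str] = set()
    if np.any(p > q):
        certs.add("10")
    if np.any(q > p):
        certs.add("01")
    if np.any(p + q > k):
        certs.add("11")
    return certs
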