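import numpy as np
import pytest

from isoturn import (
    composition_from_sequence,
    load_element_table,
    load_neh_table,
    natural_isotope_distribution,
)
from isoturn.chem import PeptideComposition


@pytest.fixture(scope="session")
def elements():
    return load_element_table()


@pytest.fixture(scope="session")
def neh_table():
    return load_neh_table()


@pytest.fixture(scope="session")
def small_peptide():
    """A short peptide with an integer N_EH override for oracle tests."""
    comp = composition_from_sequence("GTTITSVLPK", 2)
    return PeptideComposition(comp.sequence, comp.charge, comp.element_counts, 10.0)


@pytest.fixture(scope="session")
def exemplar():
    """Realistic tryptic peptide used throughout the examples."""
    return composition_from_sequence("GTTITSVLPKPALVASR", 2)


@pytest.fixture(scope="session")
def exemplar_natural(exemplar):
    return natural_isotope_distribution(exemplar)


def brute_force_distribution(element_counts, elements, n_peaks=6,
                             heavy_h=0.000115, n_heavy_sites=0, p_extra=0.0):
    """Independent exhaustive oracle: enumerate isotopologue count vectors.

    Enumerates, per element, every partition of its atoms over the
    element's isotopes (multinomial weights) and accumulates probability
    by total nominal mass shift.  Deliberately avoids the polynomial
    convolution used by the implementation.
    """
    from itertools import product
    from math import comb

    def multinomial(n, ks):
        out = 1
        rem = n
        for k in ks:
            out *= comb(rem, k)
            rem -= k
        return out

    def atom_partitions(n, probs):
        """Yield (shift, probability) for n iid atoms over isotope probs."""
        shifts = [s for s, p in enumerate(probs) if p > 0]
        ps = [probs[s] for s in shifts]
        def rec(i, left, shift, weight, counts):
            if i == len(shifts) - 1:
                counts = counts + [left]
                w = multinomial(n, counts)
                prob = weight * ps[-1] ** left
                yield shift + shifts[-1] * left, w * prob
                return
            for k in range(left + 1):
                yield from rec(i + 1, left - k, shift + shifts[i] * k,
                               weight * ps[i] ** k, counts + [k])
        yield from rec(0, n, 0, 1.0, [])

    dists = []
    for el, n in element_counts.items():
        if n == 0:
            continue
        probs = list(elements[el])
        if el == "H" and n_heavy_sites:
            probs_sub = [1.0 - (heavy_h + p_extra), heavy_h + p_extra]
            agg = {}
            for s, p in atom_partitions(n - n_heavy_sites, probs):
                agg[s] = agg.get(s, 0.0) + p
            agg2 = {}
            for s, p in atom_partitions(n_heavy_sites, probs_sub):
                agg2[s] = agg2.get(s, 0.0) + p
            merged = {}
            for s1, p1 in agg.items():
                for s2, p2 in agg2.items():
                    merged[s1 + s2] = merged.get(s1 + s2, 0.0) + p1 * p2
            dists.append(merged)
        else:
            agg = {}
            for s, p in atom_partitions(n, probs):
                agg[s] = agg.get(s, 0.0) + p
            dists.append(agg)
    total = {0: 1.0}
    for d in dists:
        nxt = {}
        for s1, p1 in total.items():
            for s2, p2 in d.items():
                nxt[s1 + s2] = nxt.get(s1 + s2, 0.0) + p1 * p2
        total = nxt
    out = np.zeros(n_peaks)
    for s, p in total.items():
        if s < n_peaks:
            out[s] = p
    return out
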