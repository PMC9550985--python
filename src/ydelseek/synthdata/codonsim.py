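"""Codon-level sequence evolution toward divergence targets.

Substitutions are placed codon-wise under the simplest model the downstream
estimators assume: uniform proposal over positions and alternative bases,
accepted into the synonymous or nonsynonymous event budget of the branch,
with stop codons rejected. Event budgets are Poisson draws around
(target rate x available sites), so NG86 estimates of the realized
sequences recover the targets in expectation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .._seq import BASES, CODON_TABLE, check_cds, codons
from ..molevo import syn_fraction
from .config import BranchParams, substream

__all__ = ["random_cds", "evolve_branch", "evolve_gametolog_trio"]

_NON_STOP = [c for c, aa in CODON_TABLE.items() if aa != "*"]


def random_cds(n_codons: int, rng: np.random.Generator, start_codon: bool = False) -> str:
    """Random stop-free CDS of ``n_codons`` codons."""
    if n_codons < 1:
        raise ValueError("need at least one codon")
    picks = rng.integers(0, len(_NON_STOP), size=n_codons)
    cods = [_NON_STOP[i] for i in picks]
    if start_codon:
        cods[0] = "ATG"
    return "".join(cods)


def _site_counts(cds: str) -> tuple[float, float]:
    s = sum(syn_fraction(c) for c in codons(cds))
    return s, 3.0 * (len(cds) // 3) - s


def evolve_branch(
    cds: str, params: BranchParams, rng: np.random.Generator, max_tries_factor: int = 2000
) -> str:
    """Evolve a CDS along one branch to its (dS, omega) target.

    Draws Poisson event budgets n_syn ~ Pois(dS * S) and
    n_non ~ Pois(dN * N) on the ancestral site counts, then applies uniform
    single-base substitutions of the required category; changes creating a
    stop codon are rejected.
    """
    check_cds(cds, "ancestor")
    seq = list(cds.upper())
    n = len(seq)
    s_sites, n_sites = _site_counts(cds)
    need_syn = int(rng.poisson(params.syn_divergence * s_sites))
    need_non = int(rng.poisson(params.nonsyn_divergence * n_sites))
    budget = max_tries_factor * (need_syn + need_non + 1)
    tries = 0
    while (need_syn or need_non) and tries < budget:
        tries += 1
        pos = int(rng.integers(0, n))
        old = seq[pos]
        alt = BASES[int(rng.integers(0, 3))]
        if alt == old:  # remap the collision: uniform over the 3 bases != old
            alt = BASES[3]
        cstart = 3 * (pos // 3)
        codon = "".join(seq[cstart : cstart + 3])
        new_codon = codon[: pos - cstart] + alt + codon[pos - cstart + 1 :]
        if CODON_TABLE[new_codon] == "*":
            continue
        synonymous = CODON_TABLE[new_codon] == CODON_TABLE[codon]
        if synonymous and need_syn:
            need_syn -= 1
        elif not synonymous and need_non:
            need_non -= 1
        else:
            continue
        seq[pos] = alt
    if need_syn or need_non:
        raise RuntimeError(
            f"could not place all substitutions ({need_syn} syn, {need_non} nonsyn left)"
        )
    return "".join(seq)


def evolve_gametolog_trio(
    ancestor_cds: str,
    branch_params: Mapping[str, BranchParams],
    seed: int,
) -> tuple[str, str, str]:
    """Evolve (x, y, outgroup) descendants of an ancestral CDS.

    ``branch_params`` must provide 'x', 'y' and 'outgroup' branches. The x
    and y branches share a gametolog ancestor identical to ``ancestor_cds``
    (a star topology at the root keeps the pairwise sums interpretable).
    """
    for name in ("x", "y", "outgroup"):
        if name not in branch_params:
            raise ValueError(f"missing branch {name!r} in branch parameters")
    check_cds(ancestor_cds, "ancestor")
    x = evolve_branch(ancestor_cds, branch_params["x"], substream(seed, 11))
    y = evolve_branch(ancestor_cds, branch_params["y"], substream(seed, 12))
    out = evolve_branch(ancestor_cds, branch_params["outgroup"], substream(seed, 13))
    return x, y, out
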