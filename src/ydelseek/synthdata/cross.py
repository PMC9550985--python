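"""Simulated two-parent cross with sexed offspring.

X-linked sites: sons are hemizygous for one maternal allele; daughters
carry one maternal allele plus the paternal X allele. Autosomal sites
follow Mendelian biallelic transmission. Site class is recorded as truth.
"""

from __future__ import annotations

from ..xlinkage import CrossGenotypes, Site
from .config import CrossConfig, substream

__all__ = ["simulate_cross"]

_ALLELES = "ACGT"


def simulate_cross(config: CrossConfig, seed: int = 0) -> CrossGenotypes:
    rng = substream(seed, 40)
    sons = [f"son{i + 1}" for i in range(config.n_sons)]
    daughters = [f"dau{i + 1}" for i in range(config.n_daughters)]
    sexes = {**{s: "M" for s in sons}, **{d: "F" for d in daughters}}

    sites: list[Site] = []
    for i in range(config.n_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        a, b = _ALLELES[int(ref)], _ALLELES[int(alt)]
        x_linked = rng.random() < 0.5
        mother = tuple(sorted(str(rng.choice([a, b])) for _ in range(2)))
        if x_linked:
            father = (str(rng.choice([a, b])),)  # single X allele
            offspring = {}
            for son in sons:
                offspring[son] = (str(rng.choice(mother)),)
            for dau in daughters:
                offspring[dau] = tuple(sorted((str(rng.choice(mother)), father[0])))
        else:
            father = tuple(sorted(str(rng.choice([a, b])) for _ in range(2)))
            offspring = {}
            for child in [*sons, *daughters]:
                offspring[child] = tuple(
                    sorted((str(rng.choice(mother)), str(rng.choice(father))))
                )
        sites.append(
            Site(
                site_id=f"s{i + 1:04d}",
                mother=mother,
                father=father,
                offspring=offspring,
                truth_class="X" if x_linked else "A",
            )
        )
    return CrossGenotypes(sexes=sexes, sites=sites)
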