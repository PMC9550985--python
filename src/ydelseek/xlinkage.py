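"""X-linkage segregation test on a two-parent family with sexed offspring.

A site is informative when the father carries an allele the mother lacks.
For an X-linked locus, sons (hemizygous) must show only a maternal allele
while daughters must carry the paternal-specific allele; any violation
rejects the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Site",
    "CrossGenotypes",
    "SiteCall",
    "XLinkageResult",
    "classify_sites",
    "xlinkage_power",
    "write_cross_tsv",
    "read_cross_tsv",
]

MISSING = "."


@dataclass(frozen=True)
class Site:
    site_id: str
    mother: tuple[str, str]
    father: tuple[str, ...]  # one allele (hemizygous X call) or two
    offspring: dict  # individual -> genotype tuple, or None when missing
    truth_class: str = ""  # 'X' or 'A' when simulated, '' otherwise


@dataclass
class CrossGenotypes:
    sexes: dict  # individual -> 'M' or 'F'
    sites: list

    @property
    def sons(self) -> list[str]:
        return [i for i, s in self.sexes.items() if s == "M"]

    @property
    def daughters(self) -> list[str]:
        return [i for i, s in self.sexes.items() if s == "F"]


@dataclass(frozen=True)
class SiteCall:
    site_id: str
    informative: bool
    consistent: bool
    violation: str = ""


@dataclass
class XLinkageResult:
    calls: list
    n_informative: int
    n_consistent: int
    verdict: str  # 'X-linked' | 'rejected' | 'uninformative'

    def as_dict(self) -> dict:
        return {
            "n_sites": len(self.calls),
            "n_informative": self.n_informative,
            "n_consistent": self.n_consistent,
            "verdict": self.verdict,
        }


def _site_call(site: Site, sexes: dict) -> SiteCall:
    maternal = set(site.mother)
    paternal_specific = [a for a in site.father if a not in maternal]
    if not paternal_specific:
        return SiteCall(site.site_id, informative=False, consistent=True)
    pat = paternal_specific[0]
    for indiv, geno in site.offspring.items():
        if geno is None:
            continue
        alleles = set(geno)
        if sexes[indiv] == "M":
            if pat in alleles:
                return SiteCall(
                    site.site_id, True, False,
                    f"son {indiv} carries paternal-specific allele {pat}",
                )
            if len(alleles) > 1:
                return SiteCall(
                    site.site_id, True, False,
                    f"son {indiv} heterozygous ({'/'.join(sorted(alleles))}); not hemizygous-compatible",
                )
            if not alleles <= maternal:
                return SiteCall(
                    site.site_id, True, False,
                    f"son {indiv} carries non-maternal allele",
                )
        else:
            if pat not in alleles:
                return SiteCall(
                    site.site_id, True, False,
                    f"daughter {indiv} lacks paternal-specific allele {pat}",
                )
    return SiteCall(site.site_id, informative=True, consistent=True)


def classify_sites(cross: CrossGenotypes) -> XLinkageResult:
    """Per-site X-consistency calls plus a locus verdict.

    Verdict is 'X-linked' when at least one informative site exists and no
    informative site violates the maternal-inheritance rule; any violation
    yields 'rejected'; no informative sites yields 'uninformative'.
    """
    if not cross.sons:
        raise ValueError("X-linkage test undefined without sons in the family")
    calls = [_site_call(site, cross.sexes) for site in cross.sites]
    informative = [c for c in calls if c.informative]
    consistent = [c for c in informative if c.consistent]
    if not informative:
        verdict = "uninformative"
    elif len(consistent) == len(informative):
        verdict = "X-linked"
    else:
        verdict = "rejected"
    return XLinkageResult(
        calls=calls,
        n_informative=len(informative),
        n_consistent=len(consistent),
        verdict=verdict,
    )


def xlinkage_power(
    n_sons: int,
    n_daughters: int,
    site_class: str = "autosomal",
    n_replicates: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo probability that an informative site of the given class
    mimics X-linkage in a family of this size, with binomial standard error.

    The informative configuration is mother A/A with the father carrying a
    B allele (heterozygous A/B for an autosomal site, hemizygous B for an
    X-linked one).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if site_class not in ("autosomal", "x-linked"):
        raise ValueError(f"unknown site class {site_class!r}")
    rng = np.random.default_rng(seed)
    n_off = n_sons + n_daughters
    if site_class == "x-linked":
        passes = n_replicates  # sons always maternal, daughters always get B
    else:
        # father transmits B with probability 1/2 to each offspring
        draws = rng.random((n_replicates, n_off)) < 0.5
        sons_ok = ~draws[:, :n_sons].any(axis=1)
        daughters_ok = draws[:, n_sons:].all(axis=1)
        passes = int((sons_ok & daughters_ok).sum())
    p = passes / n_replicates
    se = float(np.sqrt(p * (1 - p) / n_replicates))
    return p, se


# ---------------------------------------------------------------------------
# TSV round-trip


def _fmt_geno(geno) -> str:
    if geno is None:
        return MISSING
    return "/".join(geno)


def _parse_geno(text: str):
    if text == MISSING:
        return None
    return tuple(text.split("/"))


def write_cross_tsv(cross: CrossGenotypes, path) -> None:
    offspring = list(cross.sexes)
    with open(path, "w") as fh:
        fh.write("#sex\t\t\t" + "\t".join(cross.sexes[i] for i in offspring) + "\n")
        fh.write("site\tmother\tfather\t" + "\t".join(offspring))
        fh.write("\tclass\n")
        for site in cross.sites:
            cells = [site.site_id, _fmt_geno(site.mother), _fmt_geno(site.father)]
            cells += [_fmt_geno(site.offspring.get(i)) for i in offspring]
            cells.append(site.truth_class or MISSING)
            fh.write("\t".join(cells) + "\n")


def read_cross_tsv(path) -> CrossGenotypes:
    with open(path) as fh:
        sex_line = fh.readline().rstrip("\n").split("\t")
        header = fh.readline().rstrip("\n").split("\t")
        has_class = header[-1] == "class"
        offspring = header[3 : len(header) - 1 if has_class else len(header)]
        sexes = dict(zip(offspring, sex_line[3 : 3 + len(offspring)]))
        sites = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            truth = cells[-1] if has_class else MISSING
            geno_cells = cells[3 : 3 + len(offspring)]
            sites.append(
                Site(
                    site_id=cells[0],
                    mother=_parse_geno(cells[1]),
                    father=_parse_geno(cells[2]),
                    offspring={i: _parse_geno(g) for i, g in zip(offspring, geno_cells)},
                    truth_class="" if truth == MISSING else truth,
                )
            )
    return CrossGenotypes(sexes=sexes, sites=sites)
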