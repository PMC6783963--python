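"""Seeded generator of synthetic olive-germplasm datasets.

Emulates the statistical structure of a four-site Campanian olive
survey: ~169 trees across sites CE/CM/OIR/OSE with UTM coordinates,
six SSR loci of 9-13 alleles drawn under within-site Hardy-Weinberg
with optional clonal replication (copied multilocus genotypes, some
carrying 2-bp somatic variants), site-specific fatty-acid signatures
including acids structurally absent from some sites, and morphometric
means that follow the north-south gradient.  Every dataset is fully
determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    GenotypeTable,
    QuantitativeMatrix,
    SampleTable,
    write_genotypes,
    write_quantitative,
    write_sample_table,
)
from .errors import ValidationError

__all__ = [
    "SimConfig",
    "generate",
    "default_config",
    "three_profile_config",
    "strong_separation_config",
    "write_dataset",
]

# Published pooled allele-frequency profiles for the six SSR loci
# commonly used on Campanian olive germplasm (allele sizes in bp).
DEFAULT_ALLELE_FREQS: dict[str, dict[int, float]] = {
    "UDO36": {138: 0.012, 140: 0.190, 142: 0.075, 144: 0.461, 148: 0.003,
              150: 0.006, 152: 0.235, 154: 0.006, 160: 0.006, 162: 0.003, 164: 0.003},
    "UDO6": {144: 0.012, 146: 0.373, 160: 0.088, 162: 0.003, 164: 0.003,
             166: 0.006, 168: 0.158, 170: 0.055, 172: 0.252, 178: 0.003,
             180: 0.042, 188: 0.003, 190: 0.003},
    "UDO17": {144: 0.003, 150: 0.003, 152: 0.155, 154: 0.211, 156: 0.082,
              158: 0.007, 160: 0.118, 162: 0.280, 168: 0.125, 170: 0.016},
    "GAPU59": {204: 0.009, 206: 0.259, 208: 0.003, 210: 0.449, 212: 0.006,
               214: 0.003, 216: 0.098, 218: 0.003, 220: 0.164, 224: 0.006},
    "GAPU71B": {116: 0.009, 118: 0.015, 120: 0.479, 122: 0.006, 124: 0.015,
                126: 0.140, 128: 0.003, 140: 0.330, 144: 0.003},
    "UDO39": {104: 0.012, 144: 0.093, 164: 0.003, 170: 0.503, 174: 0.012,
              176: 0.166, 178: 0.024, 180: 0.160, 186: 0.006, 188: 0.018, 190: 0.003},
}

_SITES = ["CE", "CM", "OIR", "OSE"]
DEFAULT_SITE_SIZES = {"CE": 62, "CM": 33, "OIR": 48, "OSE": 26}

# Approximate UTM 33T centroids (metres): OIR northernmost (Irpinia),
# then OSE (Sele), CE (Cilento hinterland) and CM (Cilento coast).
DEFAULT_CENTROIDS = {
    "CE": (520_000.0, 4_460_000.0),
    "CM": (505_000.0, 4_430_000.0),
    "OIR": (480_000.0, 4_540_000.0),
    "OSE": (500_000.0, 4_495_000.0),
}

# Site mean (and sd) of fatty-acid relative abundance in %; a mean of
# exactly 0 is a structural zero (the acid never occurs at that site).
DEFAULT_FATTY_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "C16:0 (Palmitic)": {"CE": (12.69, 0.71), "CM": (16.35, 2.93), "OIR": (12.51, 1.97), "OSE": (10.63, 1.2)},
    "C16:1 (Palmitoleic)": {"CE": (2.23, 0.44), "CM": (0.9, 0.68), "OIR": (1.03, 0.57), "OSE": (0.54, 0.18)},
    "C17:1 (Heptadecenoic)": {"CE": (0.0, 0.0), "CM": (0.33, 0.09), "OIR": (0.04, 0.11), "OSE": (0.01, 0.02)},
    "C18:1 (Oleic)": {"CE": (72.86, 1.79), "CM": (70.72, 3.36), "OIR": (76.94, 5.14), "OSE": (80.01, 3.12)},
    "C18:1t (t-Octadecenoic)": {"CE": (3.84, 0.53), "CM": (1.49, 0.53), "OIR": (0.27, 1.06), "OSE": (0.0, 0.0)},
    "C18:2 (Linoleic)": {"CE": (7.47, 1.22), "CM": (8.06, 1.66), "OIR": (5.06, 3.46), "OSE": (6.29, 1.68)},
    "C18:3 (Linolenic)": {"CE": (0.47, 0.12), "CM": (0.68, 0.22), "OIR": (1.0, 0.38), "OSE": (0.74, 0.2)},
    "C20:0 (Eicosanoic)": {"CE": (0.45, 0.07), "CM": (0.63, 0.15), "OIR": (0.02, 0.09), "OSE": (0.0, 0.0)},
    "C20:1 (Eicosenoic)": {"CE": (0.0, 0.0), "CM": (0.0, 0.0), "OIR": (0.59, 0.2), "OSE": (0.61, 0.09)},
    "C22:0 (Behenic)": {"CE": (0.0, 0.0), "CM": (0.09, 0.03), "OIR": (0.0, 0.01), "OSE": (0.02, 0.05)},
}

DEFAULT_MORPHO_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "olive_weight_g": {"CE": (1.63, 0.37), "CM": (1.13, 0.26), "OIR": (2.12, 0.45), "OSE": (1.73, 0.23)},
    "major_axis_cm": {"CE": (1.81, 0.22), "CM": (1.71, 0.18), "OIR": (2.03, 0.26), "OSE": (1.82, 0.21)},
    "leaf_area_cm2": {"CE": (4.71, 1.06), "CM": (7.14, 1.63), "OIR": (4.72, 1.24), "OSE": (5.09, 1.32)},
}


@dataclass
class SimConfig:
    """Full specification of one synthetic germplasm dataset."""

    sites: list[str] = field(default_factory=lambda: list(_SITES))
    trees_per_site: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SITE_SIZES))
    centroids: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_CENTROIDS))
    coord_spread_m: float = 1500.0
    allele_freqs: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ALLELE_FREQS.items()}
    )
    site_differentiation: float = 3.0
    clone_fraction: float = 0.55
    somatic_variant_prob: float = 0.1
    somatic_step_bp: int = 2
    missing_rate: float = 0.03
    fatty_means: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FATTY_MEANS.items()}
    )
    morpho_means: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MORPHO_MEANS.items()}
    )
    morpho_gradient: dict[str, float] = field(default_factory=dict)
    ensure_allele_coverage: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.clone_fraction < 1:
            raise ValidationError("clone_fraction must lie in [0, 1)")
        if any(n < 1 for n in self.trees_per_site.values()):
            raise ValidationError("every site needs at least one tree")
        if self.clone_fraction > 0 and any(n < 2 for n in self.trees_per_site.values()):
            raise ValidationError("clonal replication needs >= 2 trees per site")
        for site in self.sites:
            # 0.5 slack: published site means are rounded to 2 decimals
            total = sum(self.fatty_means[acid][site][0] for acid in self.fatty_means)
            if total > 100.5:
                raise ValidationError(f"fatty-acid means at {site!r} exceed 100%")

    @property
    def loci(self) -> list[str]:
        return list(self.allele_freqs)

    @property
    def n_trees(self) -> int:
        return sum(self.trees_per_site[s] for s in self.sites)


def default_config() -> SimConfig:
    """The reference configuration: 4 sites x (62, 33, 48, 26) trees,
    6 loci with 9-13 alleles, ~55% clonal copies, published site
    fatty-acid and morphometric means."""
    return SimConfig()


def three_profile_config() -> SimConfig:
    """Variant where OSE shares OIR's fatty-acid profile exactly: three
    distinct biochemical profiles across four sites."""
    cfg = SimConfig()
    fatty = {
        acid: {**by_site, "OSE": by_site["OIR"]} for acid, by_site in cfg.fatty_means.items()
    }
    return replace(cfg, fatty_means=fatty)


def strong_separation_config() -> SimConfig:
    """Variant where every site's fatty-acid profile is pushed away from
    the across-site mean profile (contrast doubled), with tighter
    within-site noise (sd x0.25) and stronger genetic differentiation.
    Used for power/recovery checks where all four sites must be clearly
    separable; the reference configuration keeps two sites with largely
    overlapping oil profiles."""
    cfg = SimConfig()
    acids = list(cfg.fatty_means)
    amplified: dict[str, dict[str, float]] = {a: {} for a in acids}
    for acid in acids:
        by_site = cfg.fatty_means[acid]
        grand = float(np.mean([m for m, _ in by_site.values()]))
        for site, (m, _) in by_site.items():
            amplified[acid][site] = 0.0 if m == 0.0 else max(grand + 2.0 * (m - grand), 0.01)
    fatty: dict[str, dict[str, tuple[float, float]]] = {a: {} for a in acids}
    for site in cfg.sites:
        orig_total = sum(cfg.fatty_means[a][site][0] for a in acids)
        amp_total = sum(amplified[a][site] for a in acids)
        scale = orig_total / amp_total
        for acid in acids:
            sd = cfg.fatty_means[acid][site][1]
            fatty[acid][site] = (amplified[acid][site] * scale, 0.25 * sd)
    return replace(cfg, fatty_means=fatty, site_differentiation=6.0)


# ---------------------------------------------------------------------------


def _site_allele_profile(
    freqs: dict[int, float], site_idx: int, n_sites: int, strength: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tilt the pooled allele frequencies toward a site-specific region.

    Alleles are ranked by size; site s up-weights alleles whose rank
    position is near (s + 0.5) / n_sites, so different sites favour
    different parts of the allele-size spectrum while the pooled
    frequencies stay close to the input.  strength = 0 recovers the
    pooled profile for every site.
    """
    alleles = np.array(sorted(freqs))
    f = np.array([freqs[a] for a in alleles])
    pos = (np.arange(len(alleles)) + 0.5) / len(alleles)
    centre = (site_idx + 0.5) / n_sites
    w = f * np.exp(-strength * np.abs(pos - centre))
    return alleles, w / w.sum()


def generate(
    cfg: SimConfig, seed: int | None = None, with_truth: bool = False
):
    """Draw one dataset: (samples, genotypes, morphometrics, fatty acids).

    Non-clonal genotypes are sampled under Hardy-Weinberg within their
    site's tilted allele profile; a ``clone_fraction`` of each site's
    trees instead copies an earlier tree of the same site, occasionally
    shifting one allele by ±``somatic_step_bp`` (a somatic variant).
    With ``ensure_allele_coverage`` (default) every configured allele is
    planted at least once among the non-clonal founders — the
    configured pool plays the role of the survey's observed allele
    inventory.  Fatty-acid rows are site mean + truncated Gaussian
    noise, renormalised to the site's total, with structural zeros kept
    at exactly 0.  Morphometrics are site mean + noise with an optional
    within-site northing gradient.

    With ``with_truth=True`` a fifth element is returned: a dict with
    the planted genet labels (``genet_labels``, one integer per tree,
    clones of one founder share a label).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    loci = cfg.loci
    sample_ids: list[str] = []
    sites: list[str] = []
    easting: list[float] = []
    northing: list[float] = []
    all_alleles = []
    morph_rows = []
    fatty_rows = []
    genet_labels: list[int] = []
    founder_idx: list[int] = []
    acids = list(cfg.fatty_means)
    morpho_vars = list(cfg.morpho_means)

    for s_idx, site in enumerate(cfg.sites):
        n_site = cfg.trees_per_site[site]
        cx, cy = cfg.centroids[site]
        profiles = {
            locus: _site_allele_profile(
                cfg.allele_freqs[locus], s_idx, len(cfg.sites), cfg.site_differentiation
            )
            for locus in loci
        }
        site_genotypes: list[np.ndarray] = []
        site_genets: list[int] = []
        for t in range(n_site):
            sample_ids.append(f"{site}{t + 1}")
            sites.append(site)
            easting.append(cx + rng.normal(0, cfg.coord_spread_m))
            ny = cy + rng.normal(0, cfg.coord_spread_m)
            northing.append(ny)

            # --- genotype
            if site_genotypes and rng.random() < cfg.clone_fraction:
                src = int(rng.integers(len(site_genotypes)))
                geno = site_genotypes[src].copy()
                genet_labels.append(site_genets[src])
                if rng.random() < cfg.somatic_variant_prob:
                    # shift one allele to a neighbouring allele of the same
                    # pool (somatic variants stay within the observed
                    # inventory, typically 2-3 bp away)
                    j = int(rng.integers(len(loci)))
                    k = int(rng.integers(2))
                    pool = np.array(sorted(cfg.allele_freqs[loci[j]]))
                    near = pool[
                        (np.abs(pool - geno[j, k]) <= cfg.somatic_step_bp + 1)
                        & (pool != geno[j, k])
                    ]
                    if len(near):
                        geno[j, k] = int(near[rng.integers(len(near))])
            else:
                geno = np.empty((len(loci), 2), dtype=np.int64)
                for j, locus in enumerate(loci):
                    alleles, p = profiles[locus]
                    geno[j] = rng.choice(alleles, size=2, p=p)
                founder_idx.append(len(sample_ids) - 1)
                genet_labels.append(len(founder_idx) - 1)
            site_genets.append(genet_labels[-1])
            site_genotypes.append(geno)
            all_alleles.append(np.sort(geno, axis=1))

            # --- morphometrics
            row = []
            for var in morpho_vars:
                m, sd = cfg.morpho_means[var][site]
                slope = cfg.morpho_gradient.get(var, 0.0)
                row.append(max(m + slope * (ny - cy) + rng.normal(0, sd), 0.01))
            morph_rows.append(row)

            # --- fatty acids
            means = np.array([cfg.fatty_means[a][site][0] for a in acids])
            sds = np.array([cfg.fatty_means[a][site][1] for a in acids])
            vals = np.clip(means + rng.normal(0, 1, len(acids)) * sds, 0.0, None)
            vals[means == 0.0] = 0.0  # structural zeros stay absent
            total = means.sum()
            if vals.sum() > 0:
                vals = np.clip(vals * total / vals.sum(), 0.0, 100.0)
            fatty_rows.append(vals)

    alleles = np.stack(all_alleles)  # (n, L, 2)
    missing = rng.random((len(sample_ids), len(loci))) < cfg.missing_rate

    if cfg.ensure_allele_coverage and founder_idx:
        # plant any configured allele that the draw left unobserved into a
        # typed clone-free founder, so the dataset's allele inventory
        # matches the pool without breaking planted genets
        labels_arr = np.array(genet_labels)
        sizes = {int(l): int(c) for l, c in zip(*np.unique(labels_arr, return_counts=True))}
        lone = [i for i in founder_idx if sizes[genet_labels[i]] == 1]
        for _ in range(5):
            planted = False
            for j, locus in enumerate(loci):
                typed = ~missing[:, j]
                seen = set(np.unique(alleles[typed, j, :])) if typed.any() else set()
                absent = [a for a in sorted(cfg.allele_freqs[locus]) if a not in seen]
                hosts = [i for i in (lone or founder_idx) if not missing[i, j]]
                if not hosts:
                    continue
                for a in absent:
                    i = hosts[int(rng.integers(len(hosts)))]
                    alleles[i, j, int(rng.integers(2))] = a
                    alleles[i, j] = np.sort(alleles[i, j])
                    planted = True
            if not planted:
                break

    samples = SampleTable(sample_ids, sites, np.array(easting), np.array(northing))
    genotypes = GenotypeTable(list(sample_ids), loci, alleles, missing)
    morpho = QuantitativeMatrix(
        pd.DataFrame(morph_rows, index=pd.Index(sample_ids, name="sample_id"), columns=morpho_vars)
    )
    fatty = QuantitativeMatrix(
        pd.DataFrame(
            np.vstack(fatty_rows), index=pd.Index(sample_ids, name="sample_id"), columns=acids
        ),
        percent=True,
    )
    if with_truth:
        truth = {"genet_labels": np.array(genet_labels), "founders": list(founder_idx)}
        return samples, genotypes, morpho, fatty, truth
    return samples, genotypes, morpho, fatty


def write_dataset(out_dir, cfg: SimConfig, seed: int | None = None) -> dict[str, Path]:
    """Generate and write the four CSVs in the schemas the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, genotypes, morpho, fatty = generate(cfg, seed=seed)
    paths = {
        "samples": out / "samples.csv",
        "genotypes": out / "genotypes.csv",
        "morphometrics": out / "morphometrics.csv",
        "fatty_acids": out / "fatty_acids.csv",
    }
    write_sample_table(samples, paths["samples"])
    write_genotypes(genotypes, paths["genotypes"])
    write_quantitative(morpho, paths["morphometrics"])
    write_quantitative(fatty, paths["fatty_acids"])
    return paths
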