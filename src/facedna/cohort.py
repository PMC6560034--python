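"""Synthetic cohorts with known genetic and covariate effects on 3D faces.

The generator emulates the ingredients the matching pipeline needs, with
ground truth recorded for parameter-recovery tests:

* structured genotypes under a Balding-Nichols model — per-SNP ancestral
  frequencies, per-population frequencies drawn from the Beta
  parameterization with population-specific Fst, individual ancestry
  proportions from a Dirichlet, genotypes binomial in the mixed frequency;
* an unadmixed reference panel spanning the same SNPs, whose PCA defines
  the genomic-background space;
* covariates (sex coded +1 female / -1 male, age, height, weight and hence
  BMI);
* 3D faces built from a bilaterally symmetric template plus spatially
  smooth per-predictor displacement fields (sex, age, BMI, ancestry
  proportions, causal-SNP dosages), spatially correlated Gaussian noise,
  and a random rigid motion plus scale jitter so Procrustes alignment is
  non-trivial.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from facedna._rng import substream
from facedna.shape import LandmarkConfiguration

__all__ = [
    "PopulationModel",
    "EffectField",
    "SyntheticCohort",
    "make_face_template",
    "smooth_effect_field",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_faces",
    "simulate_cohort",
    "genomic_background_pcs",
    "write_cohort",
    "read_cohort",
]


@dataclass
class PopulationModel:
    """Balding-Nichols population structure parameters."""

    n_populations: int
    fst_per_population: tuple[float, ...]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    admixture_concentration: float = 0.5

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        self.fst_per_population = tuple(float(f) for f in self.fst_per_population)
        if len(self.fst_per_population) != self.n_populations:
            raise ValueError("need one Fst per population")
        if any(not (0.0 < f < 1.0) for f in self.fst_per_population):
            raise ValueError("Fst values must lie in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if self.admixture_concentration < 0:
            raise ValueError("admixture_concentration must be >= 0")


@dataclass
class EffectField:
    """Ground-truth displacement field tied to one predictor.

    ``predictor`` names the per-individual covariate driving the field:
    ``sex``, ``age``, ``bmi``, ``ancestry:<k>`` or ``snp:<id>``.  The
    displacement is stored with unit per-coordinate RMS, so
    ``effect_scale`` is the RMS landmark displacement (in template
    coordinate units) caused by one standard-deviation change of the
    predictor.
    """

    feature_name: str
    predictor: str
    displacement: np.ndarray  # (L, 3), unit per-coordinate RMS
    effect_scale: float

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 2 or self.displacement.shape[1] != 3:
            raise ValueError("displacement must be (L, 3)")

    def contribution(self, predictor_values: np.ndarray) -> np.ndarray:
        """(N, L, 3) displacement; identically zero when effect_scale is 0."""
        v = np.asarray(predictor_values, float)
        return self.effect_scale * v[:, None, None] * self.displacement[None]


@dataclass
class SyntheticCohort:
    """A fully specified study cohort with ground truth."""

    genotypes: np.ndarray  # (N, S) float dosages; NaN = missing
    reference_genotypes: np.ndarray  # (M, S) int dosages
    snp_table: pd.DataFrame  # id, chrom, pos, ref, alt
    covariates: pd.DataFrame  # id, sex, age, height, weight, bmi
    ancestry: np.ndarray  # (N, K)
    faces: np.ndarray | None = None  # (N, L, 3)
    template: LandmarkConfiguration | None = None
    effects: list[EffectField] = field(default_factory=list)
    causal_snps: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        g = self.genotypes
        finite = g[np.isfinite(g)]
        if finite.size and not np.all(np.isin(finite, [0.0, 1.0, 2.0])):
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")
        if not np.all(np.isin(self.covariates["sex"].to_numpy(), [1, -1])):
            raise ValueError("sex must be coded +1 (female) / -1 (male)")
        if len(self.covariates) != g.shape[0]:
            raise ValueError("covariate rows must match individuals")
        if self.faces is not None and self.faces.shape[0] != g.shape[0]:
            raise ValueError("every individual needs a face")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def ids(self) -> list[str]:
        return list(self.covariates["id"].astype(str))


# --------------------------------------------------------------------------
# face template


def make_face_template(
    n_landmarks: int = 250, seed: int = 0, midline_fraction: float = 0.1
) -> LandmarkConfiguration:
    """A bilaterally symmetric face-like landmark template.

    Landmarks are spread over a half-ellipsoid patch (a stylized facial
    mask) with a midline ridge standing in for the nasal profile.  The
    first axis is sagittal: midline landmarks sit at x = 0 and every other
    landmark has an exact mirror partner.  Coordinates are in arbitrary
    units with centroid size of order one.
    """
    if n_landmarks < 9:
        raise ValueError("need at least 9 landmarks")
    rng = substream(seed, "face-template")
    n_mid = max(3, int(round(midline_fraction * n_landmarks)))
    if (n_landmarks - n_mid) % 2:
        n_mid += 1
    n_half = (n_landmarks - n_mid) // 2

    def surface(u, v):
        # u in (0,1): lateral parameter; v in (0,1): vertical parameter
        x = 0.9 * u
        y = 1.1 * (v - 0.5)
        z = 0.55 * np.sqrt(np.clip(1.0 - u**2 - (2 * (v - 0.5)) ** 2 * 0.55, 0.0, None))
        z = z + 0.25 * np.exp(-((u / 0.18) ** 2) - (((v - 0.45) / 0.16) ** 2))
        return np.stack([x, y, z], axis=-1)

    # stratified jittered sampling keeps the coverage even yet seeded
    u_half = np.sqrt(rng.uniform(0.02, 1.0, n_half))
    v_half = rng.uniform(0.02, 0.98, n_half)
    right = surface(u_half, v_half)
    left = right.copy()
    left[:, 0] = -left[:, 0]
    v_mid = np.linspace(0.03, 0.97, n_mid) + rng.uniform(-0.01, 0.01, n_mid)
    mid = surface(np.zeros(n_mid), v_mid)
    mid[:, 0] = 0.0

    coords = np.concatenate([right, left, mid], axis=0)
    coords -= coords.mean(axis=0)
    pairs = np.stack([np.arange(n_half), n_half + np.arange(n_half)], axis=1)
    midline = 2 * n_half + np.arange(n_mid)
    ids = (
        [f"R{i}" for i in range(n_half)]
        + [f"L{i}" for i in range(n_half)]
        + [f"M{i}" for i in range(n_mid)]
    )
    return LandmarkConfiguration(
        coordinates=coords, landmark_ids=ids, pairs=pairs, midline=midline
    )


def _spatial_kernel(template: LandmarkConfiguration, bandwidth: float) -> np.ndarray:
    """Squared-exponential correlation over template inter-landmark distance."""
    X = template.coordinates
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    K = np.exp(-d2 / (2.0 * bandwidth**2))
    return K + 1e-8 * np.eye(len(X))


def smooth_effect_field(
    template: LandmarkConfiguration,
    feature_name: str,
    predictor: str,
    effect_scale: float,
    bandwidth: float = 0.25,
    seed: int = 0,
    symmetric: bool = True,
) -> EffectField:
    """Draw a spatially smooth random displacement field on the template.

    The field is a kernel-smoothed Gaussian draw, optionally symmetrized
    across the sagittal plane, normalized to unit per-coordinate RMS.
    """
    rng = substream(seed, f"effect-field-{feature_name}")
    chol = np.linalg.cholesky(_spatial_kernel(template, bandwidth))
    disp = chol @ rng.standard_normal((template.n_landmarks, 3))
    if symmetric:
        perm = template.reflection_permutation()
        mirrored = disp[perm].copy()
        mirrored[:, 0] = -mirrored[:, 0]
        disp = 0.5 * (disp + mirrored)
    rms = np.sqrt(np.mean(disp**2))
    if rms < 1e-12:
        raise ValueError("degenerate effect field")
    return EffectField(
        feature_name=feature_name,
        predictor=predictor,
        displacement=disp / rms,
        effect_scale=float(effect_scale),
    )


# --------------------------------------------------------------------------
# genotypes and covariates

_ALLELES = ["A", "C", "G", "T"]


def _snp_positions(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    n_chrom = min(22, max(1, n_snps // 50))
    chrom = np.sort(rng.integers(1, n_chrom + 1, n_snps))
    pos = np.empty(n_snps, dtype=int)
    for c in range(1, n_chrom + 1):
        idx = np.flatnonzero(chrom == c)
        gaps = rng.integers(5_000, 80_000, len(idx))
        pos[idx] = 10_000 + np.cumsum(gaps)
    ref_i = rng.integers(0, 4, n_snps)
    alt_i = (ref_i + rng.integers(1, 4, n_snps)) % 4
    return pd.DataFrame(
        {
            "id": [f"snp{i:05d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "ref": [_ALLELES[i] for i in ref_i],
            "alt": [_ALLELES[i] for i in alt_i],
        }
    )


def simulate_genotypes(
    model: PopulationModel,
    n_individuals: int,
    n_panel: int,
    n_snps: int,
    seed: int,
    missing_rate: float = 0.0,
) -> SyntheticCohort:
    """Structured genotypes for study individuals and a reference panel.

    Study individuals are admixed (Dirichlet ancestry proportions over the
    populations); panel individuals are unadmixed and balanced across
    populations, so panel PCs span between-population structure the way a
    reference-population panel does.  Returns a cohort whose face fields
    are not yet filled.
    """
    if min(n_individuals, n_panel, n_snps) < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = substream(seed, "genotypes")
    K = model.n_populations
    lo, hi = model.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, n_snps)
    pop_freq = np.empty((K, n_snps))
    for k, F in enumerate(model.fst_per_population):
        if F < 1e-12:
            pop_freq[k] = p_anc
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            pop_freq[k] = rng.beta(a, b)
    pop_freq = np.clip(pop_freq, 1e-4, 1.0 - 1e-4)

    alpha = model.admixture_concentration
    if alpha <= 0:
        Q = np.zeros((n_individuals, K))
        Q[np.arange(n_individuals), rng.integers(0, K, n_individuals)] = 1.0
    else:
        Q = rng.dirichlet(np.full(K, alpha), size=n_individuals)
    freq = Q @ pop_freq
    G = rng.binomial(2, freq).astype(float)
    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = np.nan

    panel_pop = np.arange(n_panel) % K
    panel = rng.binomial(2, pop_freq[panel_pop])

    snp_table = _snp_positions(n_snps, rng)
    covs = simulate_covariates(n_individuals, seed)
    return SyntheticCohort(
        genotypes=G,
        reference_genotypes=panel,
        snp_table=snp_table,
        covariates=covs,
        ancestry=Q,
        seed=seed,
    )


def simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Sex (+1 female / -1 male), age (years), height (m), weight (kg), BMI."""
    rng = substream(seed, "covariates")
    sex = np.where(rng.random(n) < 0.5, 1, -1)
    age = rng.uniform(18.0, 70.0, n)
    height = 1.70 - 0.07 * sex + rng.normal(0.0, 0.06, n)
    bmi = np.clip(rng.normal(24.7, 3.5, n), 16.0, 45.0)
    weight = bmi * height**2
    return pd.DataFrame(
        {
            "id": [f"ind{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "bmi": bmi,
        }
    )


def _predictor_values(cohort: SyntheticCohort, predictor: str) -> np.ndarray:
    """Resolve an effect predictor to centered per-individual values."""
    cov = cohort.covariates
    if predictor == "sex":
        return cov["sex"].to_numpy(float)
    if predictor in ("age", "bmi"):
        v = cov[predictor].to_numpy(float)
        return (v - v.mean()) / v.std()
    if predictor.startswith("ancestry:"):
        k = int(predictor.split(":", 1)[1])
        v = cohort.ancestry[:, k]
        return v - v.mean()
    if predictor.startswith("snp:"):
        sid = predictor.split(":", 1)[1]
        j = int(np.flatnonzero(cohort.snp_table["id"] == sid)[0])
        v = cohort.genotypes[:, j].copy()
        m = np.nanmean(v)
        v[~np.isfinite(v)] = m
        sd = v.std()
        return (v - m) / (sd if sd > 0 else 1.0)
    raise ValueError(f"unknown predictor {predictor!r}")


def simulate_faces(
    cohort: SyntheticCohort,
    template: LandmarkConfiguration,
    effects: list[EffectField],
    noise_sd: float,
    seed: int,
    noise_bandwidth: float = 0.25,
    rigid_motion: bool = True,
    scale_jitter_sd: float = 0.05,
) -> np.ndarray:
    """Generate faces: template + effects + correlated noise + rigid motion.

    Noise is Gaussian with a squared-exponential spatial correlation over
    the template geometry (marginal standard deviation ``noise_sd`` per
    coordinate).  A random rigid motion and log-normal scale jitter make
    Procrustes superimposition non-trivial.
    """
    rng = substream(seed, "faces")
    L = template.n_landmarks
    N = cohort.n_individuals
    faces = np.broadcast_to(template.coordinates, (N, L, 3)).copy()
    for eff in effects:
        if eff.displacement.shape[0] != L:
            raise ValueError(
                f"effect field {eff.feature_name!r} has {eff.displacement.shape[0]}"
                f" landmarks, template has {L}"
            )
        faces += eff.contribution(_predictor_values(cohort, eff.predictor))
    if noise_sd > 0:
        chol = np.linalg.cholesky(_spatial_kernel(template, noise_bandwidth))
        z = rng.standard_normal((N, L, 3))
        faces += noise_sd * np.einsum("lm,nmk->nlk", chol, z)
    if rigid_motion:
        size = np.linalg.norm(template.coordinates - template.coordinates.mean(0))
        for i in range(N):
            A = rng.standard_normal((3, 3))
            Qr, _ = np.linalg.qr(A)
            if np.linalg.det(Qr) < 0:
                Qr[:, 0] = -Qr[:, 0]
            s = float(np.exp(rng.normal(0.0, scale_jitter_sd)))
            t = rng.normal(0.0, 0.2 * size / np.sqrt(L), 3)
            faces[i] = s * faces[i] @ Qr + t
    return faces


# --------------------------------------------------------------------------
# one-call cohort with default study conditions


def default_effects(
    template: LandmarkConfiguration,
    cohort: SyntheticCohort,
    n_causal_snps: int,
    noise_sd: float,
    seed: int,
    sex_scale: float = 0.5,
    age_scale: float = 0.2,
    bmi_scale: float = 0.2,
    ancestry_scale: float = 0.5,
    snp_scale: float = 0.15,
    bandwidth: float = 0.25,
) -> tuple[list[EffectField], list[str]]:
    """Standard effect inventory; scales are multiples of ``noise_sd``.

    Causal SNPs are drawn evenly across the SNP panel.  A scale of zero
    drops the corresponding field entirely.
    """
    effects: list[EffectField] = []

    def add(name, predictor, rel_scale, tag):
        if rel_scale > 0:
            effects.append(
                smooth_effect_field(
                    template, name, predictor, rel_scale * noise_sd,
                    bandwidth=bandwidth, seed=seed + tag,
                )
            )

    add("sex", "sex", sex_scale, 101)
    add("age", "age", age_scale, 102)
    add("bmi", "bmi", bmi_scale, 103)
    for k in range(cohort.ancestry.shape[1]):
        add(f"ancestry{k}", f"ancestry:{k}", ancestry_scale, 200 + k)
    n_snps = cohort.n_snps
    step = max(1, n_snps // max(n_causal_snps, 1))
    causal_ids: list[str] = []
    for c in range(n_causal_snps):
        j = (c * step + step // 2) % n_snps
        sid = str(cohort.snp_table["id"].iloc[j])
        causal_ids.append(sid)
        add(f"snp_{sid}", f"snp:{sid}", snp_scale, 300 + c)
    return effects, causal_ids


def simulate_cohort(
    n_individuals: int = 600,
    n_panel: int = 300,
    n_snps: int = 2000,
    n_causal_snps: int = 10,
    n_landmarks: int = 250,
    model: PopulationModel | None = None,
    noise_sd: float = 0.05,
    noise_bandwidth: float = 0.25,
    seed: int = 0,
    missing_rate: float = 0.0,
    **effect_scales,
) -> SyntheticCohort:
    """Simulate a complete cohort (genotypes, covariates, faces, truth)."""
    if model is None:
        model = PopulationModel(
            n_populations=3,
            fst_per_population=(0.15, 0.15, 0.15),
            ancestral_maf_range=(0.05, 0.5),
            admixture_concentration=0.5,
        )
    cohort = simulate_genotypes(
        model, n_individuals, n_panel, n_snps, seed, missing_rate=missing_rate
    )
    template = make_face_template(n_landmarks, seed=seed)
    effects, causal = default_effects(
        template, cohort, n_causal_snps, noise_sd, seed,
        bandwidth=noise_bandwidth, **effect_scales,
    )
    cohort.template = template
    cohort.effects = effects
    cohort.causal_snps = causal
    cohort.faces = simulate_faces(
        cohort, template, effects, noise_sd, seed, noise_bandwidth=noise_bandwidth
    )
    return cohort


def genomic_background_pcs(
    genotypes: np.ndarray, panel: np.ndarray, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project study genotypes into the panel-defined PCA space.

    PCA is computed on the column-centered panel genotypes only, so the
    shape of the space is defined exclusively by the reference panel; study
    individuals (missing dosages imputed to the panel mean) are projected
    into it.  Returns (study_scores, panel_scores).
    """
    P = np.asarray(panel, float)
    mu = P.mean(axis=0)
    Pc = P - mu
    U, s, Vt = np.linalg.svd(Pc, full_matrices=False)
    nd = int(np.sum(s > 1e-9 * s[0]))
    if n_components is not None:
        nd = min(nd, n_components)
    G = np.array(genotypes, float, copy=True)
    miss = ~np.isfinite(G)
    if miss.any():
        G[miss] = np.broadcast_to(mu, G.shape)[miss]
    return (G - mu) @ Vt[:nd].T, U[:, :nd] * s[:nd]


# --------------------------------------------------------------------------
# on-disk round trip (VCF + coordinate tables + CSV + JSON)


def _write_vcf(path: Path, dosages: np.ndarray, snp_table: pd.DataFrame, ids: list[str]) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(snp_table["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for j, row in enumerate(snp_table.itertuples(index=False)):
            cells = [
                str(row.chrom), str(row.pos), row.id, row.ref, row.alt,
                ".", "PASS", ".", "GT",
            ]
            col = dosages[:, j]
            cells += [
                "./." if not np.isfinite(g) else gt_map[int(g)] for g in col
            ]
            fh.write("\t".join(cells) + "\n")


def _read_vcf(path: Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for v in vcf:
        rows.append((v.ID, int(v.CHROM), v.POS, v.REF, v.ALT[0]))
        gt = v.gt_types.astype(float)  # with gts012: 0,1,2 and 3=unknown
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
    table = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    return np.column_stack(dosage_cols), table, samples


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as plain-text artifacts; returns the manifest.

    Layout: ``genotypes.vcf`` and ``panel.vcf`` (VCF v4.2, GT only),
    ``faces/<id>.xyz`` whitespace-delimited coordinate tables,
    ``covariates.csv``, ``template.json`` (coordinates + pairing),
    ``truth.json`` (causal SNP ids, effect fields, ancestry), and
    ``manifest.json``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ids = cohort.ids
    _write_vcf(d / "genotypes.vcf", cohort.genotypes, cohort.snp_table, ids)
    panel_ids = [f"panel{i:05d}" for i in range(len(cohort.reference_genotypes))]
    _write_vcf(d / "panel.vcf", cohort.reference_genotypes.astype(float),
               cohort.snp_table, panel_ids)
    cohort.covariates.to_csv(d / "covariates.csv", index=False)
    if cohort.faces is not None:
        face_dir = d / "faces"
        face_dir.mkdir(exist_ok=True)
        for i, ind in enumerate(ids):
            np.savetxt(face_dir / f"{ind}.xyz", cohort.faces[i], fmt="%.10g")
    if cohort.template is not None:
        t = cohort.template
        with open(d / "template.json", "w") as fh:
            json.dump(
                {
                    "coordinates": t.coordinates.tolist(),
                    "landmark_ids": t.landmark_ids,
                    "pairs": t.pairs.tolist(),
                    "midline": t.midline.tolist(),
                },
                fh,
            )
    with open(d / "truth.json", "w") as fh:
        json.dump(
            {
                "causal_snps": cohort.causal_snps,
                "ancestry": cohort.ancestry.tolist(),
                "effects": [
                    {
                        "feature_name": e.feature_name,
                        "predictor": e.predictor,
                        "effect_scale": e.effect_scale,
                        "displacement": e.displacement.tolist(),
                    }
                    for e in cohort.effects
                ],
            },
            fh,
        )
    manifest = {
        "seed": cohort.seed,
        "n_individuals": cohort.n_individuals,
        "n_snps": cohort.n_snps,
        "n_panel": int(cohort.reference_genotypes.shape[0]),
        "has_faces": cohort.faces is not None,
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    d = Path(directory)
    G, snp_table, ids = _read_vcf(d / "genotypes.vcf")
    panel, _, _ = _read_vcf(d / "panel.vcf")
    covs = pd.read_csv(d / "covariates.csv")
    covs["id"] = covs["id"].astype(str)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    template = None
    if (d / "template.json").exists():
        with open(d / "template.json") as fh:
            t = json.load(fh)
        template = LandmarkConfiguration(
            coordinates=np.asarray(t["coordinates"]),
            landmark_ids=t["landmark_ids"],
            pairs=np.asarray(t["pairs"]),
            midline=np.asarray(t["midline"]),
        )
    faces = None
    if (d / "faces").exists():
        faces = np.stack(
            [np.loadtxt(d / "faces" / f"{ind}.xyz") for ind in covs["id"]]
        )
    effects = [
        EffectField(
            feature_name=e["feature_name"],
            predictor=e["predictor"],
            displacement=np.asarray(e["displacement"]),
            effect_scale=e["effect_scale"],
        )
        for e in truth["effects"]
    ]
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    return SyntheticCohort(
        genotypes=G,
        reference_genotypes=panel.astype(int),
        snp_table=snp_table,
        covariates=covs,
        ancestry=np.asarray(truth["ancestry"]),
        faces=faces,
        template=template,
        effects=effects,
        causal_snps=list(truth["causal_snps"]),
        seed=manifest.get("seed"),
    )
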