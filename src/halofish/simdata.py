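"""Forward simulation of Halo-FISH experiments with full ground truth.

The simulator emulates the computational tail of the assay: a deproteinized
nucleus whose chromosomal DNA stays in an intensely DAPI-stained *nuclear
core* while extrachromosomal telomere-repeat (ECTR) molecules have diffused
into the surrounding *Halo*.  Each single-stranded molecule is rendered as a
point emitter whose expected photon flux is proportional to its
telomere-repeat length in base pairs, blurred by a separable 3D Gaussian PSF,
and read out through a Poisson–Gaussian camera model with 12-bit
quantization.  Calibration-slide fields of isolated plasmid foci (135- and
270-repeat inserts, i.e. 810 and 1620 bp of telomere sequence) are simulated
with the same optics, so the downstream intensity-to-length calibration can
be exercised end to end against known truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .stack import CHANNELS, ImageStack

logger = logging.getLogger(__name__)

#: Base pairs per hexameric telomere repeat (TTAGGG / AATCCC).
BP_PER_REPEAT = 6

#: Fixed camera offset added to every voxel (ADU).
CAMERA_OFFSET_ADU = 100.0

_PHASES = ("G1", "S", "G2")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and camera model for rendered stacks.

    Defaults follow the assay's acquisition geometry: 40 z-planes at 0.2 µm
    spacing, 12-bit grayscale, with a 0.16 µm xy pixel pitch (40x objective).
    ``photons_per_bp`` sets the expected photon yield per base pair of
    hybridized probe target; at the default 0.25 the 810-bp calibration
    standard is detected essentially always (integrated signal-to-noise
    ~5.6:1 at focus scale) while a 200-kb molecule still peaks below 12-bit
    saturation — mirroring the assay's own operating point, where the 810-bp
    standard defines the reliable minimum and molecules a few hundred bp
    long sit at a 2:1 signal-to-noise ratio.
    """

    field_size_voxels: tuple[int, int, int] = (40, 144, 144)  # z, y, x
    voxel_size_um: tuple[float, float, float] = (0.2, 0.16, 0.16)
    bit_depth: int = 12
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.12, 0.12)
    photons_per_bp: float = 0.25
    background_level: float = 4.0  # mean background photons/voxel, per channel
    read_noise_sd: float = 1.0  # ADU
    dapi_core_photons: float = 800.0  # photons/voxel inside the core body
    dapi_halo_photons: float = 3.0  # faint DAPI floor outside the core
    saturation_warn_fraction: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.field_size_voxels) != 3 or any(
            int(s) <= 0 for s in self.field_size_voxels
        ):
            raise ValueError("field_size_voxels must be three positive counts")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("PSF sigmas must be positive")
        if not (math.isfinite(self.photons_per_bp) and self.photons_per_bp > 0):
            raise ValueError("photons_per_bp must be positive and finite")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def max_adu(self) -> float:
        return float(2**self.bit_depth - 1)

    def field_size_um(self) -> tuple[float, float, float]:
        return tuple(
            n * v for n, v in zip(self.field_size_voxels, self.voxel_size_um)
        )

    def psf_sigma_voxels(self) -> tuple[float, float, float]:
        return tuple(s / v for s, v in zip(self.psf_sigma_um, self.voxel_size_um))


@dataclass(frozen=True)
class CellLinePreset:
    """Per-cell-line generative parameters.

    ``ectr_count_mean_G``/``_C`` are mean detectable ECTR molecules per
    nucleus; counts are over-dispersed (negative-binomial with dispersion
    ``ectr_count_dispersion``, shared between strands through a common total)
    so per-nucleus counts range from under 20 to over 300 in strongly ALT
    lines.  Molecule lengths are log-normal (``length_logmean``/``length_logsd``
    in log-bp), reproducing the strong positive skew of observed ECTR length
    distributions.  ``g_strand_number_bias`` records the empirical fraction of
    nuclei with more G- than C-strand molecules that the preset aims to
    reproduce (it is descriptive; the bias emerges from the mean asymmetry).
    Chromosomal telomere lengths and centromere probe brightness (expressed in
    telomere-bp equivalents) parameterize the nuclear-core foci.
    """

    name: str
    ectr_count_mean_G: float
    ectr_count_mean_C: float
    ectr_count_dispersion: float = 5.0
    length_logmean: float = math.log(10_000.0)
    length_logsd: float = 1.25
    g_strand_number_bias: float = 0.5
    chromosome_count: int = 46
    telomere_length_mean_bp: float = 80_000.0
    telomere_length_sd_bp: float = 60_000.0
    cen_equiv_bp_mean: float = 3_000.0
    cen_equiv_bp_sd: float = 500.0
    ectr_count_g2_fold: float = 3.5
    ectr_length_g2_fold: float = 1.226

    def __post_init__(self) -> None:
        for name in (
            "ectr_count_mean_G",
            "ectr_count_mean_C",
            "ectr_count_dispersion",
            "length_logmean",
            "length_logsd",
            "telomere_length_mean_bp",
            "telomere_length_sd_bp",
            "cen_equiv_bp_mean",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.ectr_count_mean_G < 0 or self.ectr_count_mean_C < 0:
            raise ValueError("ECTR count means must be >= 0")
        if self.ectr_count_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.chromosome_count < 2 or self.chromosome_count % 2:
            raise ValueError("chromosome_count must be even and >= 2")
        if not 0.0 <= self.g_strand_number_bias <= 1.0:
            raise ValueError("g_strand_number_bias must be in [0, 1]")

    def scaled(self, count_factor: float = 1.0, length_factor: float = 1.0):
        """Preset with ECTR count means and length scale multiplied."""
        return replace(
            self,
            ectr_count_mean_G=self.ectr_count_mean_G * count_factor,
            ectr_count_mean_C=self.ectr_count_mean_C * count_factor,
            length_logmean=self.length_logmean + math.log(length_factor),
        )


#: Packaged ALT cell-line presets.  Count means are the observed per-nucleus
#: averages for each line; length parameters reproduce each line's published
#: length-bin fractions and 2–2.5x mean/median skew.
GM847 = CellLinePreset(
    name="GM847",
    ectr_count_mean_G=126.0,
    ectr_count_mean_C=95.0,
    ectr_count_dispersion=5.0,
    length_logmean=math.log(10_000.0),
    length_logsd=1.25,
    g_strand_number_bias=0.90,
    telomere_length_mean_bp=80_000.0,
    telomere_length_sd_bp=60_000.0,
    ectr_count_g2_fold=3.5,
)
VA13 = CellLinePreset(
    name="VA13",
    ectr_count_mean_G=59.0,
    ectr_count_mean_C=44.0,
    ectr_count_dispersion=5.0,
    length_logmean=math.log(14_000.0),
    length_logsd=1.25,
    g_strand_number_bias=0.617,
    telomere_length_mean_bp=60_000.0,
    telomere_length_sd_bp=45_000.0,
    ectr_count_g2_fold=2.7,
)
U2OS = CellLinePreset(
    name="U2OS",
    ectr_count_mean_G=21.0,
    ectr_count_mean_C=14.0,
    ectr_count_dispersion=4.0,
    length_logmean=math.log(45_000.0),
    length_logsd=1.32,
    g_strand_number_bias=0.823,
    telomere_length_mean_bp=150_000.0,
    telomere_length_sd_bp=100_000.0,
    ectr_count_g2_fold=4.9,
)

PRESETS: dict[str, CellLinePreset] = {p.name: p for p in (GM847, VA13, U2OS)}


def null_preset(base: CellLinePreset = GM847) -> CellLinePreset:
    """A preset with zero ECTR molecules (chromosomal foci only)."""
    return replace(base, name=base.name + "-null", ectr_count_mean_G=0.0,
                   ectr_count_mean_C=0.0)


# ---------------------------------------------------------------------------
# ground-truth types
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """One telomere-repeat DNA emitter in the simulated field."""

    strand: str  # "G" | "C" | "duplex"
    repeat_length_bp: float
    position_um: tuple[float, float, float] | None = None  # z, y, x
    compartment_truth: str = "halo"  # "core" | "halo"

    def __post_init__(self) -> None:
        if self.strand not in ("G", "C", "duplex"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not (self.repeat_length_bp > 0 and math.isfinite(self.repeat_length_bp)):
            raise ValueError("repeat_length_bp must be positive and finite")
        if self.compartment_truth not in ("core", "halo"):
            raise ValueError("compartment_truth must be 'core' or 'halo'")


@dataclass
class NucleusGeometry:
    """Placement geometry for one simulated nucleus."""

    core_center_um: tuple[float, float, float]
    core_radius_um: float = 3.5
    halo_offset_um: float = 0.6  # clearance between core edge and nearest ECTR
    halo_scale_um: float = 3.0  # half-normal scale of the radial diffusion profile
    border_margin_um: tuple[float, float, float] = (1.0, 1.0, 1.0)


def default_geometry(config: SimConfig) -> NucleusGeometry:
    center = tuple(s / 2.0 for s in config.field_size_um())
    return NucleusGeometry(core_center_um=center)


@dataclass
class GroundTruth:
    """Complete generative record for one simulated stack."""

    nucleus_id: str
    core_center_um: tuple[float, float, float] | None
    core_radius_um: float
    molecules: list[Molecule]
    centromere_positions_um: list[tuple[float, float, float]] = field(
        default_factory=list
    )
    centromere_equiv_bp: list[float] = field(default_factory=list)
    cell_cycle_truth: str | None = None

    def ectr_molecules(self) -> list[Molecule]:
        return [m for m in self.molecules if m.compartment_truth == "halo"]

    def ectr_count(self, strand: str) -> int:
        return sum(1 for m in self.ectr_molecules() if m.strand == strand)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        mols = [Molecule(**m) for m in d["molecules"]]
        d = dict(d)
        d["molecules"] = mols
        if d.get("core_center_um") is not None:
            d["core_center_um"] = tuple(d["core_center_um"])
        d["centromere_positions_um"] = [
            tuple(p) for p in d.get("centromere_positions_um", [])
        ]
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_ectr_population(
    preset: CellLinePreset,
    n_nuclei: int,
    seed=None,
) -> list[list[Molecule]]:
    """Draw per-nucleus ECTR molecule populations (positions unset).

    The total molecule count per nucleus is negative-binomial with mean
    ``mean_G + mean_C`` and dispersion ``ectr_count_dispersion``; each
    molecule is independently assigned G- or C-strand with probability
    ``mean_G / (mean_G + mean_C)``.  The shared total makes G and C counts
    positively correlated across nuclei, matching the strong per-cell
    variability of ALT lines, while the Bernoulli strand assignment produces
    the observed G-strand number bias.  Lengths are log-normal.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    rng = _as_rng(seed)
    total_mean = preset.ectr_count_mean_G + preset.ectr_count_mean_C
    out: list[list[Molecule]] = []
    for _ in range(n_nuclei):
        if total_mean == 0:
            out.append([])
            continue
        r = preset.ectr_count_dispersion
        n_total = int(rng.negative_binomial(r, r / (r + total_mean)))
        p_g = preset.ectr_count_mean_G / total_mean
        strands = np.where(rng.random(n_total) < p_g, "G", "C")
        lengths = rng.lognormal(
            mean=preset.length_logmean, sigma=preset.length_logsd, size=n_total
        )
        out.append(
            [
                Molecule(strand=str(s), repeat_length_bp=float(l))
                for s, l in zip(strands, lengths)
            ]
        )
    return out


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) from arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd <= 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _uniform_in_sphere(rng, center, radius, n) -> np.ndarray:
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(center)[None, :] + pts * r[:, None]


def build_nucleus_truth(
    preset: CellLinePreset,
    ectr_molecules: Sequence[Molecule],
    cell_cycle_phase: str,
    geometry: NucleusGeometry,
    config: SimConfig,
    seed=None,
    nucleus_id: str = "nucleus-0",
    max_retries: int = 200,
) -> GroundTruth:
    """Place chromosomal core foci and Halo ECTR molecules in the field.

    Chromosomal telomeres (2 per chromosome, one G- and one C-strand focus
    each, near-coincident) and centromeres are placed uniformly inside the
    core sphere.  ECTR molecules are placed in the Halo: direction uniform on
    the sphere, distance from the core edge = clearance + half-normal draw;
    placements outside the in-field margins are re-drawn (bounded retries).
    S phase replicates a random fraction of chromosomes; G2 doubles both
    centromere and core-telomere entries.
    """
    if cell_cycle_phase not in _PHASES:
        raise ValueError(f"cell_cycle_phase must be one of {_PHASES}")
    rng = _as_rng(seed)
    field_um = config.field_size_um()
    lo = np.asarray(geometry.border_margin_um, dtype=float)
    hi = np.asarray(field_um, dtype=float) - lo
    center = np.asarray(geometry.core_center_um, dtype=float)
    radius = float(geometry.core_radius_um)

    if np.any(center - radius < 0) or np.any(center + radius > field_um):
        raise ValueError("core sphere does not fit the field of view")

    n_chrom = preset.chromosome_count
    if cell_cycle_phase == "G1":
        n_extra = 0
    elif cell_cycle_phase == "G2":
        n_extra = n_chrom
    else:  # S: a random replicated fraction
        n_extra = int(rng.binomial(n_chrom, rng.uniform(0.2, 0.8)))

    molecules: list[Molecule] = []

    # chromosomal telomeres: 2 per chromosome copy, each contributing a
    # near-coincident G and C single-strand focus after denaturation
    n_tel = 2 * (n_chrom + n_extra)
    tel_mu, tel_sigma = _lognormal_params(
        preset.telomere_length_mean_bp, preset.telomere_length_sd_bp
    )
    tel_pos = _uniform_in_sphere(rng, center, radius * 0.97, n_tel)
    tel_len = rng.lognormal(tel_mu, tel_sigma, size=n_tel)
    for pos, ln in zip(tel_pos, tel_len):
        for strand in ("G", "C"):
            jitter = rng.normal(0.0, 0.05, size=3)
            molecules.append(
                Molecule(
                    strand=strand,
                    repeat_length_bp=float(ln),
                    position_um=tuple(pos + jitter),
                    compartment_truth="core",
                )
            )

    n_cen = n_chrom + n_extra
    cen_pos = _uniform_in_sphere(rng, center, radius * 0.97, n_cen)
    cen_bp = np.clip(
        rng.normal(preset.cen_equiv_bp_mean, preset.cen_equiv_bp_sd, size=n_cen),
        preset.cen_equiv_bp_mean * 0.2,
        None,
    )

    # Halo placement: radial diffusion profile away from the core edge
    for mol in ectr_molecules:
        placed = False
        for _ in range(max_retries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = geometry.halo_offset_um + abs(rng.normal(0.0, geometry.halo_scale_um))
            pos = center + direction * (radius + dist)
            if np.all(pos >= lo) and np.all(pos <= hi):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place Halo molecule within {max_retries} retries; "
                "field too small for the geometry"
            )
        mol.position_um = tuple(float(v) for v in pos)
        mol.compartment_truth = "halo"
        molecules.append(mol)

    return GroundTruth(
        nucleus_id=nucleus_id,
        core_center_um=tuple(float(v) for v in center),
        core_radius_um=radius,
        molecules=molecules,
        centromere_positions_um=[tuple(float(v) for v in p) for p in cen_pos],
        centromere_equiv_bp=[float(b) for b in cen_bp],
        cell_cycle_truth=cell_cycle_phase,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _deposit_points(
    canvas: np.ndarray,
    positions_um: np.ndarray,
    photons: np.ndarray,
    voxel_size_um: Sequence[float],
) -> None:
    """Trilinear deposition of point fluxes onto a voxel grid (in place)."""
    if len(positions_um) == 0:
        return
    # voxel i spans [i, i+1) * voxel_size, center at (i + 0.5) * voxel_size
    pos_vox = np.asarray(positions_um, dtype=float) / np.asarray(voxel_size_um) - 0.5
    base = np.floor(pos_vox).astype(int)
    frac = pos_vox - base
    shape = np.asarray(canvas.shape)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                corner = base + np.array([dz, dy, dx])
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                ok = np.all((corner >= 0) & (corner < shape), axis=1)
                np.add.at(
                    canvas,
                    (corner[ok, 0], corner[ok, 1], corner[ok, 2]),
                    photons[ok] * w[ok],
                )


def _core_body(config: SimConfig, center_um, radius_um: float) -> np.ndarray:
    """Boolean mask of the solid DAPI core sphere on the voxel grid."""
    nz, ny, nx = config.field_size_voxels
    dz, dy, dx = config.voxel_size_um
    z = (np.arange(nz) + 0.5) * dz - center_um[0]
    y = (np.arange(ny) + 0.5) * dy - center_um[1]
    x = (np.arange(nx) + 0.5) * dx - center_um[2]
    r2 = (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    )
    return r2 <= radius_um**2


def render_stack(
    truth: GroundTruth,
    config: SimConfig,
    rng=None,
    noise: bool = True,
) -> ImageStack:
    """Render a 4-channel stack from ground truth.

    Each molecule contributes ``photons_per_bp * repeat_length_bp`` expected
    photons spread by the Gaussian PSF; duplex molecules emit in both
    telomere channels.  The DAPI channel renders the core as a bright solid
    body plus a faint Halo floor.  With ``noise=True`` the expected photon
    image passes through Poisson shot noise, the fixed camera offset,
    Gaussian read noise, rounding and clipping to ``bit_depth``; with
    ``noise=False`` the noiseless expectation (plus background and offset) is
    returned un-quantized, which keeps per-molecule flux exactly conserved.
    """
    rng = _as_rng(config.rng_seed if rng is None else rng)
    shape = tuple(int(s) for s in config.field_size_voxels)
    sigma_vox = config.psf_sigma_voxels()

    canvases = {name: np.zeros(shape, dtype=np.float32) for name in CHANNELS}

    by_channel: dict[str, list[tuple[tuple, float]]] = {c: [] for c in CHANNELS}
    for mol in truth.molecules:
        if mol.position_um is None:
            raise ValueError("molecule has no position; build truth first")
        flux = config.photons_per_bp * mol.repeat_length_bp
        targets = (
            ["TelC", "TelG"] if mol.strand == "duplex"
            else ["TelG" if mol.strand == "G" else "TelC"]
        )
        for t in targets:
            by_channel[t].append((mol.position_um, flux))
    for pos, bp in zip(truth.centromere_positions_um, truth.centromere_equiv_bp):
        by_channel["CEN"].append((pos, config.photons_per_bp * bp))

    for name, items in by_channel.items():
        if not items:
            continue
        positions = np.array([p for p, _ in items], dtype=float)
        photons = np.array([f for _, f in items], dtype=float)
        _deposit_points(canvases[name], positions, photons, config.voxel_size_um)

    if truth.core_center_um is not None and truth.core_radius_um > 0:
        body = _core_body(config, truth.core_center_um, truth.core_radius_um)
        canvases["DAPI"][body] += config.dapi_core_photons
        canvases["DAPI"] += config.dapi_halo_photons

    planes = []
    saturated = 0
    total = 0
    for name in CHANNELS:
        expected = ndimage.gaussian_filter(
            canvases[name], sigma=sigma_vox, mode="constant", truncate=5.0
        )
        expected += config.background_level
        if noise:
            img = rng.poisson(expected).astype(np.float64)
            img += CAMERA_OFFSET_ADU
            if config.read_noise_sd > 0:
                img += rng.normal(0.0, config.read_noise_sd, size=img.shape)
            img = np.rint(img)
        else:
            img = expected + CAMERA_OFFSET_ADU
        np.clip(img, 0.0, config.max_adu, out=img)
        saturated += int(np.count_nonzero(img >= config.max_adu))
        total += img.size
        planes.append(img.astype(np.float32))

    frac = saturated / total
    if frac > config.saturation_warn_fraction:
        logger.warning(
            "saturation fraction %.2e exceeds limit %.2e for %s",
            frac,
            config.saturation_warn_fraction,
            truth.nucleus_id,
        )

    return ImageStack(
        voxels=np.stack(planes),
        voxel_size_um=config.voxel_size_um,
        bit_depth=config.bit_depth,
        channel_names=CHANNELS,
    )


# ---------------------------------------------------------------------------
# calibration slides
# ---------------------------------------------------------------------------


def simulate_calibration_slide(
    insert_repeats: int,
    n_foci: int,
    config: SimConfig,
    seed=None,
    noise: bool = True,
    min_separation_um: float = 2.0,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a slide seeded with plasmid calibration standards.

    Each focus is a duplex plasmid insert of ``6 * insert_repeats`` bp of
    telomere sequence (both strand probes hybridize), scattered on an empty
    field (no DAPI core) with a minimum pairwise separation so the standards
    stay isolated.
    """
    if insert_repeats <= 0:
        raise ValueError("insert_repeats must be positive")
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    rng = _as_rng(seed)
    field_um = np.asarray(config.field_size_um())
    # generous z margin: the measurement aperture is deepest along z and
    # z-clipped standards would bias the calibration low
    margin = np.array([1.5, 1.0, 1.0])
    lo, hi = margin, field_um - margin
    if np.any(hi <= lo):
        raise ValueError("field too small for calibration foci")

    positions: list[np.ndarray] = []
    rejections = 0  # consecutive failures: the field is saturated
    while len(positions) < n_foci:
        if rejections >= 2000:
            raise RuntimeError(
                f"cannot place {n_foci} non-overlapping foci "
                f"(min separation {min_separation_um} um) in this field"
            )
        cand = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(cand - p) >= min_separation_um for p in positions):
            positions.append(cand)
            rejections = 0
        else:
            rejections += 1

    bp = float(BP_PER_REPEAT * insert_repeats)
    molecules = [
        Molecule(
            strand="duplex",
            repeat_length_bp=bp,
            position_um=tuple(float(v) for v in p),
            compartment_truth="halo",
        )
        for p in positions
    ]
    truth = GroundTruth(
        nucleus_id=f"std-{insert_repeats}rep",
        core_center_um=None,
        core_radius_um=0.0,
        molecules=molecules,
        cell_cycle_truth=None,
    )
    stack = render_stack(truth, config, rng=rng, noise=noise)
    return stack, truth


# ---------------------------------------------------------------------------
# experiment-level convenience
# ---------------------------------------------------------------------------

#: Phase mix used for asynchronously growing cultures.
ASYNC_PHASE_PROBS = {"G1": 0.5, "S": 0.3, "G2": 0.2}


def _phase_factors(preset: CellLinePreset, phase: str) -> tuple[float, float]:
    """(count multiplier, length multiplier) for a cell-cycle phase."""
    if phase == "G1":
        return 1.0, 1.0
    if phase == "G2":
        return preset.ectr_count_g2_fold, preset.ectr_length_g2_fold
    cf = 1.0 + (preset.ectr_count_g2_fold - 1.0) * 0.5
    lf = 1.0 + (preset.ectr_length_g2_fold - 1.0) * 0.5
    return cf, lf


def simulate_nucleus(
    preset: CellLinePreset,
    phase: str,
    config: SimConfig,
    seed=None,
    nucleus_id: str = "nucleus-0",
    geometry: NucleusGeometry | None = None,
    noise: bool = True,
) -> tuple[GroundTruth, ImageStack]:
    """Sample, place and render one nucleus in the given cell-cycle phase."""
    rng = _as_rng(seed)
    geometry = geometry or default_geometry(config)
    cf, lf = _phase_factors(preset, phase)
    mols = sample_ectr_population(preset.scaled(cf, lf), 1, seed=rng)[0]
    truth = build_nucleus_truth(
        preset, mols, phase, geometry, config, seed=rng, nucleus_id=nucleus_id
    )
    stack = render_stack(truth, config, rng=rng, noise=noise)
    return truth, stack


def simulate_experiment(
    preset: CellLinePreset,
    n_nuclei: int,
    config: SimConfig,
    seed=None,
    phases: str | Sequence[str] = "asynchronous",
    noise: bool = True,
) -> Iterator[tuple[GroundTruth, ImageStack]]:
    """Yield ``n_nuclei`` simulated (truth, stack) pairs.

    ``phases`` is either a phase name applied to every nucleus ("G1", "S",
    "G2"), "asynchronous" for the packaged asynchronous-culture mix, or an
    explicit sequence of per-nucleus phases.
    """
    rng = _as_rng(seed)
    if isinstance(phases, str):
        if phases == "asynchronous":
            names = list(ASYNC_PHASE_PROBS)
            probs = np.array([ASYNC_PHASE_PROBS[n] for n in names])
            phase_list = [
                names[i] for i in rng.choice(len(names), size=n_nuclei, p=probs)
            ]
        else:
            phase_list = [phases] * n_nuclei
    else:
        phase_list = list(phases)
        if len(phase_list) != n_nuclei:
            raise ValueError("phases sequence length must equal n_nuclei")
    for i, phase in enumerate(phase_list):
        yield simulate_nucleus(
            preset,
            phase,
            config,
            seed=rng,
            nucleus_id=f"{preset.name}-{i:03d}",
            noise=noise,
        )
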