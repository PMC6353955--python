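"""Ground-truthed synthetic data for every pipeline stage.

Each generator emulates the raw material of one analysis: two-compartment
metaphase cells with a known chromosome/cytoplasm intensity ratio, FRAP
traces following the single-exponential recovery model plus acquisition
bleaching, single-molecule localization tables with planted per-class
binding, three-density interphase nuclei with a planted TF enrichment
profile, and protein cohorts whose log-MBF follows a sparse linear model
on the extracted sequence features.  Every artifact carries the seed and
the full parameter set that produced it, and its truth values are
recomputable from those parameters in closed form.

Noise is additive Gaussian throughout (optionally Poisson for images);
images are single-precision grayscale with the pixel size carried as
metadata (default 0.05 um/px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from . import frap as _frap
from . import mbf as _mbf
from . import seqfeat as _seq
from .smtrack import SCHEME_FRAME_S

DEFAULT_PIXEL_SIZE_UM = 0.05

#: DBD family pool for synthetic cohorts (15 families so that, with the
#: >10-record rule, a 500-record cohort yields 15 one-hot columns and a
#: ~50-column design matrix overall).
DBD_FAMILY_POOL = tuple(
    f"family_{i:02d}" for i in range(15)
)


@dataclass
class GroundTruth:
    """Provenance of a synthetic artifact: stage, parameters and seed."""

    stage: str
    params: dict
    seed: int | None


# ---------------------------------------------------------------------------
# metaphase cells


@dataclass
class CellGeometry:
    """Ellipse model of a metaphase cell and its chromosome plate (pixels)."""

    shape: tuple[int, int] = (256, 256)
    cell_center: tuple[float, float] = (128.0, 128.0)
    cell_axes: tuple[float, float] = (80.0, 66.0)
    chrom_axes: tuple[float, float] = (34.0, 14.0)
    rotation: float = 0.0

    def validate(self) -> None:
        r, c = self.cell_center
        a = max(self.cell_axes)
        if r - a < 0 or c - a < 0 or r + a >= self.shape[0] or c + a >= self.shape[1]:
            raise ValueError("cell geometry does not fit the image frame")
        if max(self.chrom_axes) >= min(self.cell_axes):
            raise ValueError("chromosome plate larger than the cell")


@dataclass
class SyntheticMetaphase:
    dna: np.ndarray
    tf: np.ndarray
    chromosome_mask: np.ndarray
    cell_mask: np.ndarray
    true_mbf: float
    pixel_size: float
    truth: GroundTruth


def gen_metaphase_cell(
    s_chrom_true: float,
    s_cyto_true: float,
    geometry: CellGeometry | None = None,
    noise_sd: float = 0.0,
    dna_level: float = 1000.0,
    poisson_noise: bool = False,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int | None = None,
) -> SyntheticMetaphase:
    """Two-channel metaphase cell with known compartment intensities.

    The DNA channel is bright (``dna_level``) only on the chromosome-plate
    ellipse; the TF channel carries ``s_chrom_true`` on the plate,
    ``s_cyto_true`` on the rest of the cell ellipse and 0 outside.  The
    true MBF follows from the planted intensities and the fixed volume
    fractions via the same two-compartment bookkeeping as the estimator.
    """
    if s_chrom_true < 0 or s_cyto_true < 0:
        raise ValueError("intensities must be non-negative")
    geometry = geometry or CellGeometry()
    geometry.validate()
    rng = np.random.default_rng(seed)

    cell_mask = np.zeros(geometry.shape, dtype=bool)
    rr, cc = ellipse(
        *geometry.cell_center, *geometry.cell_axes,
        shape=geometry.shape, rotation=geometry.rotation,
    )
    cell_mask[rr, cc] = True
    chrom_mask = np.zeros(geometry.shape, dtype=bool)
    rr, cc = ellipse(
        *geometry.cell_center, *geometry.chrom_axes,
        shape=geometry.shape, rotation=geometry.rotation,
    )
    chrom_mask[rr, cc] = True

    dna = np.where(chrom_mask, dna_level, 0.0)
    tf = np.where(chrom_mask, s_chrom_true, np.where(cell_mask, s_cyto_true, 0.0))
    if poisson_noise:
        dna = rng.poisson(dna).astype(float)
        tf = rng.poisson(tf).astype(float)
    if noise_sd > 0:
        dna = dna + rng.normal(0, noise_sd, dna.shape)
        tf = tf + rng.normal(0, noise_sd, tf.shape)

    true_mbf = _mbf.compute_mbf(s_chrom_true, s_cyto_true)
    truth = GroundTruth(
        stage="metaphase",
        params={
            "s_chrom_true": s_chrom_true,
            "s_cyto_true": s_cyto_true,
            "noise_sd": noise_sd,
            "dna_level": dna_level,
            "pixel_size": pixel_size,
        },
        seed=seed,
    )
    return SyntheticMetaphase(
        dna=dna.astype(np.float32),
        tf=tf.astype(np.float32),
        chromosome_mask=chrom_mask,
        cell_mask=cell_mask,
        true_mbf=true_mbf,
        pixel_size=pixel_size,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# FRAP traces


@dataclass
class SyntheticFRAP:
    trace: _frap.FRAPTrace
    i0: float
    a: float
    beta: float
    t_half: float
    imof: float
    truth: GroundTruth


def gen_frap_trace(
    i0: float,
    a: float,
    beta: float,
    n_pre: int = 5,
    dt: float = 0.38,
    duration: float = 74.0,
    noise_sd: float = 0.0,
    acq_bleach_rate: float = 0.0,
    bg_level: float = 0.05,
    seed: int | None = None,
) -> SyntheticFRAP:
    """Three-ROI FRAP trace following ``I0 - a*exp(-beta*t)`` recovery.

    Pre-bleach frames sit at 1.0 (before noise and acquisition bleaching);
    both the bleached and the control ROI decay with ``acq_bleach_rate``
    (s^-1), which the double normalization cancels exactly; the background
    ROI is constant at ``bg_level``.  Default timing matches a typical
    confocal protocol (5 pre-bleach frames, 0.38-s intervals, 74-s
    recovery).
    """
    if not (0 < a <= i0 <= 1):
        raise ValueError("need 0 < a <= I0 <= 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    if n_pre < 1:
        raise ValueError("need at least one pre-bleach frame")
    rng = np.random.default_rng(seed)

    n_post = int(round(duration / dt))
    t = np.arange(n_pre + n_post) * dt
    t_post = t[n_pre:] - t[n_pre]
    model = np.concatenate([np.ones(n_pre), i0 - a * np.exp(-beta * t_post)])
    decay = np.exp(-acq_bleach_rate * t)
    roi1 = model * decay + bg_level
    roi2 = decay + bg_level
    bg = np.full_like(t, bg_level)
    if noise_sd > 0:
        roi1 = roi1 + rng.normal(0, noise_sd, t.size)
        roi2 = roi2 + rng.normal(0, noise_sd, t.size)
        bg = bg + rng.normal(0, noise_sd, t.size)

    trace = _frap.FRAPTrace(t=t, i_roi1=roi1, i_roi2=roi2, i_bg=bg, n_pre=n_pre)
    truth = GroundTruth(
        stage="frap",
        params={
            "i0": i0, "a": a, "beta": beta, "n_pre": n_pre, "dt": dt,
            "duration": duration, "noise_sd": noise_sd,
            "acq_bleach_rate": acq_bleach_rate, "bg_level": bg_level,
        },
        seed=seed,
    )
    return SyntheticFRAP(
        trace=trace,
        i0=i0,
        a=a,
        beta=beta,
        t_half=_frap.half_time(beta),
        imof=_frap.immobile_fraction(i0, a),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# single-molecule datasets


def _concentric_class_map(
    class_areas_um2: tuple[float, float, float], pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Label map (1 dark outer, 2 intermediate, 3 bright inner) and nucleus mask."""
    a_bright, a_inter, a_dark = class_areas_um2
    r3 = math.sqrt(sum(class_areas_um2) / math.pi)
    r2 = math.sqrt((a_bright + a_inter) / math.pi)
    r1 = math.sqrt(a_bright / math.pi)
    r3_px = r3 / pixel_size_um
    side = 2 * int(math.ceil(r3_px)) + 9
    c = side / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    rad = np.hypot(yy - c, xx - c) * pixel_size_um
    labels = np.zeros((side, side), dtype=np.uint8)
    labels[rad < r3] = 1
    labels[rad < r2] = 2
    labels[rad < r1] = 3
    return labels, labels > 0


@dataclass
class SMDataset:
    locs: pd.DataFrame  # molecule_id, frame, x, y (nm), intensity
    class_maps: dict[int, np.ndarray]
    nucleus_mask: np.ndarray
    class_areas: dict[str, float]  # um^2 (realized, from the label map)
    pixel_size_um: float
    scheme: str
    frame_interval_s: float
    t_recording: float
    n_molecules: int
    true_psi_on: dict[str, float]
    psi_on_se: dict[str, float]
    true_tau_res: float
    truth: GroundTruth


def _detection_count_pmf(tau: float | None, dt: float, n_frames: int) -> np.ndarray:
    """P(molecule bound from frame 0 is detected in exactly m frames), m=0..F.

    Dwell time is Exp(tau) (``tau=None`` = bound for the whole movie); the
    molecule is detected at frame k while still bound at time k*dt, so
    m = min(floor(dwell/dt)+1, F).
    """
    pmf = np.zeros(n_frames + 1)
    if tau is None or math.isinf(tau):
        pmf[n_frames] = 1.0
        return pmf
    q = math.exp(-dt / tau)
    for m in range(1, n_frames):
        pmf[m] = q ** (m - 1) - q**m
    pmf[n_frames] = q ** (n_frames - 1)
    return pmf


def gen_sm_dataset(
    n_molecules: int = 1000,
    bound_fraction_per_class: tuple[float, float, float] = (0.3, 0.15, 0.05),
    tau_mean: float | None = None,
    d_free: float = 5.0,  # um^2/s
    scheme: str = "i",
    loc_error_nm: float = 10.0,
    class_areas: tuple[float, float, float] = (20.0, 40.0, 60.0),  # bright/inter/dark um^2
    frame_count: int = 100,
    free_detect_prob: float = 0.1,
    pixel_size_um: float = 0.1,
    seed: int | None = None,
) -> SMDataset:
    """Mixture of chromatin-bound and freely diffusing emitters.

    The nucleus is partitioned into three concentric Hoechst classes of
    the given areas (bright innermost).  Per-class molecule counts are
    deterministic (area-proportional); each molecule binds with its
    class's probability.  Bound molecules sit at a fixed point (localized
    every frame with ``loc_error_nm`` jitter) for an Exp(``tau_mean``)
    dwell starting at frame 0 (``tau_mean=None``: bound throughout), then
    diffuse.  Free molecules random-walk with ``d_free`` and are localized
    with probability ``free_detect_prob`` per frame — fast diffusers are
    motion-blurred under 50-ms exposures, so their detection efficiency is
    far below that of bound molecules.

    The planted pseudo on-rate and residence time are computed in closed
    form from the parameters under the scheme's frame timing (they neglect
    criterion breakage by localization jitter, accurate for
    ``loc_error_nm`` well below the 80-nm event radius, and the rare
    spurious events of free molecules).
    """
    if any(not 0 <= p <= 1 for p in bound_fraction_per_class):
        raise ValueError("bound fractions must lie in [0, 1]")
    if any(a <= 0 for a in class_areas):
        raise ValueError("class areas must be positive")
    if scheme not in SCHEME_FRAME_S:
        raise ValueError(f"unknown illumination scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    dt = SCHEME_FRAME_S[scheme]
    t_recording = frame_count * dt

    labels, nucleus = _concentric_class_map(class_areas, pixel_size_um)
    px_area = pixel_size_um**2
    realized_areas = {
        "bright": float((labels == 3).sum() * px_area),
        "intermediate": float((labels == 2).sum() * px_area),
        "dark": float((labels == 1).sum() * px_area),
    }
    nm_per_px = pixel_size_um * 1000.0
    side_nm = labels.shape[0] * nm_per_px

    total_area = sum(class_areas)
    n_class = [int(round(n_molecules * a / total_area)) for a in class_areas]
    n_class[-1] = n_molecules - sum(n_class[:-1])

    # eroded per-class pixel lists so the 80-nm event disc stays in class
    from scipy import ndimage as _ndi

    margin_px = max(int(math.ceil(100.0 / nm_per_px)), 1)
    class_pixels = {}
    for lab in (1, 2, 3):
        core = _ndi.binary_erosion(labels == lab, iterations=margin_px)
        if not core.any():
            core = labels == lab
        class_pixels[lab] = np.argwhere(core)

    rows = []
    n_bound_planted = 0
    pmf = _detection_count_pmf(tau_mean, dt, frame_count)
    m_support = np.arange(frame_count + 1)
    step_sd_nm = math.sqrt(2.0 * d_free * dt) * 1000.0

    mol_id = 0
    for lab, n_c, p_bound in zip((3, 2, 1), n_class, bound_fraction_per_class):
        for _ in range(n_c):
            bound = rng.random() < p_bound
            if bound:
                n_bound_planted += 1
                px = class_pixels[lab][rng.integers(len(class_pixels[lab]))]
                pos = (np.array([px[1], px[0]], dtype=float) + 0.5) * nm_per_px
                m = int(rng.choice(m_support, p=pmf))
                for k in range(m):
                    jitter = rng.normal(0, loc_error_nm, 2) if loc_error_nm > 0 else 0.0
                    xy = pos + jitter
                    rows.append((mol_id, k, xy[0], xy[1], 1.0))
                # after unbinding the molecule diffuses like a free one
                cur = pos.copy()
                for k in range(m, frame_count):
                    cur = cur + rng.normal(0, step_sd_nm, 2)
                    if rng.random() < free_detect_prob and 0 <= cur[0] < side_nm and 0 <= cur[1] < side_nm:
                        rows.append((mol_id, k, cur[0], cur[1], 1.0))
            else:
                px = class_pixels[lab][rng.integers(len(class_pixels[lab]))]
                cur = (np.array([px[1], px[0]], dtype=float) + 0.5) * nm_per_px
                for k in range(frame_count):
                    if k > 0:
                        cur = cur + rng.normal(0, step_sd_nm, 2)
                    if rng.random() < free_detect_prob and 0 <= cur[0] < side_nm and 0 <= cur[1] < side_nm:
                        xy = cur + (rng.normal(0, loc_error_nm, 2) if loc_error_nm > 0 else 0.0)
                        rows.append((mol_id, k, xy[0], xy[1], 1.0))
            mol_id += 1

    locs = pd.DataFrame(rows, columns=["molecule_id", "frame", "x", "y", "intensity"])
    locs = locs.sort_values(["molecule_id", "frame"]).reset_index(drop=True)

    # closed-form truth under the detection timing
    p_event = float(pmf[2:].sum())  # P(>= 2 detections while bound)
    true_psi, psi_se = {}, {}
    for name, area, n_c, p_bound in zip(
        ("bright", "intermediate", "dark"), class_areas, n_class, bound_fraction_per_class
    ):
        pq = p_bound * p_event
        denom = realized_areas[name] * n_molecules * t_recording
        true_psi[name] = n_c * pq / denom
        psi_se[name] = math.sqrt(n_c * pq * (1 - pq)) / denom

    # expected measured bound duration per bound molecule, scheme timing
    if scheme == "i":
        e_dur = float(np.sum(m_support[2:] * pmf[2:])) * dt
    else:
        e_dur = float(np.sum((m_support[2:] - 1) * pmf[2:])) * dt
    exp_n_bound = sum(n_c * p for n_c, p in zip(n_class, bound_fraction_per_class))
    true_tau = exp_n_bound * e_dur / n_molecules

    truth = GroundTruth(
        stage="sm",
        params={
            "n_molecules": n_molecules,
            "bound_fraction_per_class": tuple(bound_fraction_per_class),
            "tau_mean": tau_mean,
            "d_free": d_free,
            "scheme": scheme,
            "loc_error_nm": loc_error_nm,
            "class_areas": tuple(class_areas),
            "frame_count": frame_count,
            "free_detect_prob": free_detect_prob,
            "pixel_size_um": pixel_size_um,
        },
        seed=seed,
    )
    return SMDataset(
        locs=locs,
        class_maps={0: labels},
        nucleus_mask=nucleus,
        class_areas=realized_areas,
        pixel_size_um=pixel_size_um,
        scheme=scheme,
        frame_interval_s=dt,
        t_recording=t_recording,
        n_molecules=n_molecules,
        true_psi_on=true_psi,
        psi_on_se=psi_se,
        true_tau_res=true_tau,
        truth=truth,
    )


def render_spot_frame(
    positions_px: list[tuple[float, float]],
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 200.0,
    psf_sigma_px: float = 1.3,
    bg_level: float = 10.0,
    noise_sd: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render diffraction-limited spots ((x, y) pixel positions) on a noisy frame."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, bg_level, dtype=float)
    for x0, y0 in positions_px:
        img += amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * psf_sigma_px**2)
        )
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, shape)
    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# interphase nuclei


@dataclass
class SyntheticNucleus:
    dna: np.ndarray
    tf: np.ndarray
    label_map: np.ndarray  # 1 high, 2 medium, 3 low Hoechst (0 outside)
    nucleus_mask: np.ndarray
    true_fractions: dict[str, float]
    pixel_size: float
    truth: GroundTruth


def gen_interphase_nucleus(
    region_fractions: tuple[float, float, float] = (0.2, 0.5, 0.3),
    hoechst_levels: tuple[float, float, float] = (300.0, 150.0, 60.0),
    tf_enrichment: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    tf_base_level: float = 100.0,
    radius_px: int = 60,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int | None = None,
) -> SyntheticNucleus:
    """Disc nucleus with three concentric chromatin-density regions.

    Triples are ordered (high, medium, low) Hoechst density; the brightest
    region is innermost.  ``hoechst_levels`` must be strictly decreasing
    (otherwise the classes are unidentifiable).  The TF channel carries
    ``tf_base_level * enrichment`` in each region, so the true per-region
    TF signal fractions are the enrichment-area products normalized to 1.
    """
    fr = np.asarray(region_fractions, dtype=float)
    if fr.min() <= 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("region fractions must be positive and sum to 1")
    lv = np.asarray(hoechst_levels, dtype=float)
    if not (lv[0] > lv[1] > lv[2]):
        raise ValueError("hoechst levels must be strictly decreasing (high > medium > low)")
    enr = np.asarray(tf_enrichment, dtype=float)
    if enr.min() < 0:
        raise ValueError("enrichment must be non-negative")
    rng = np.random.default_rng(seed)

    side = 2 * radius_px + 21
    c = side / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    rad = np.hypot(yy - c, xx - c)
    r1 = radius_px * math.sqrt(fr[0])
    r2 = radius_px * math.sqrt(fr[0] + fr[1])
    labels = np.zeros((side, side), dtype=np.uint8)
    labels[rad < radius_px] = 3
    labels[rad < r2] = 2
    labels[rad < r1] = 1
    nucleus = labels > 0

    dna = np.zeros((side, side), dtype=float)
    tf = np.zeros((side, side), dtype=float)
    for i in range(3):
        dna[labels == i + 1] = lv[i]
        tf[labels == i + 1] = tf_base_level * enr[i]
    if noise_sd > 0:
        dna += rng.normal(0, noise_sd, dna.shape)
        tf += rng.normal(0, noise_sd, tf.shape)

    weights = enr * fr
    if weights.sum() == 0:
        raise ValueError("all-zero TF signal: enrichment zero everywhere")
    true_fracs = dict(zip(("high", "medium", "low"), weights / weights.sum()))
    truth = GroundTruth(
        stage="interphase",
        params={
            "region_fractions": tuple(fr),
            "hoechst_levels": tuple(lv),
            "tf_enrichment": tuple(enr),
            "noise_sd": noise_sd,
            "tf_base_level": tf_base_level,
            "radius_px": radius_px,
        },
        seed=seed,
    )
    return SyntheticNucleus(
        dna=dna.astype(np.float32),
        tf=tf.astype(np.float32),
        label_map=labels,
        nucleus_mask=nucleus,
        true_fractions=true_fracs,
        pixel_size=pixel_size,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# protein cohorts


@dataclass
class SyntheticCohort:
    records: list[_seq.ProteinRecord]
    features: _seq.FeatureMatrix
    log_mbf: np.ndarray
    planted_coefs: dict[str, float]
    noise_sd: float
    signal_sd: float
    truth: GroundTruth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    probs = rng.dirichlet(np.full(20, 3.0))
    idx = rng.choice(20, size=length, p=probs)
    return "".join(_seq.AA_ALPHABET[i] for i in idx)


def _random_disorder_mask(rng: np.random.Generator, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for _ in range(rng.poisson(4)):
        dom_len = 6 + rng.geometric(1 / 12.0)
        start = rng.integers(0, max(length - dom_len, 1))
        mask[start : start + dom_len] = True
    return mask


def gen_protein_cohort(
    n: int = 501,
    planted_coefs: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    snr: float | None = None,
    intercept: float = math.log(0.18),
    length_range: tuple[int, int] = (200, 600),
    category_map: dict | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Protein cohort whose log(MBF) is a sparse linear model of its features.

    Sequences are drawn with per-protein Dirichlet residue compositions so
    the planted features vary across the cohort; disorder masks and DBD
    intervals (with families from a 15-member pool) are generated and
    stored on each record.  ``log(MBF) = intercept + X_norm . coefs +
    N(0, noise_sd^2)`` where ``X_norm`` is the normalized feature matrix;
    ``snr`` (sd of the planted signal over the noise sd), when given,
    overrides ``noise_sd``.
    """
    if n < 20:
        raise ValueError("need at least 20 proteins")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(*length_range))
        seq = _random_sequence(rng, length)
        n_dbd = 2 if rng.random() < 0.15 else 1
        intervals = []
        for _ in range(n_dbd):
            dbd_len = int(rng.integers(40, 90))
            start = int(rng.integers(0, length - dbd_len))
            fam = DBD_FAMILY_POOL[rng.integers(len(DBD_FAMILY_POOL))]
            intervals.append((start, start + dbd_len, fam))
        records.append(
            _seq.ProteinRecord(
                tf_id=f"TF{i:04d}",
                sequence=seq,
                dbd_intervals=intervals,
                disorder_mask=_random_disorder_mask(rng, length),
            )
        )

    matrix = _seq.build_feature_matrix(records, category_map=category_map)
    planted_coefs = dict(planted_coefs or {})
    unknown = set(planted_coefs) - set(matrix.feature_names)
    if unknown:
        raise ValueError(f"planted coefficients on unknown features: {sorted(unknown)}")

    signal = np.zeros(len(matrix.values))
    for name, coef in planted_coefs.items():
        signal = signal + coef * matrix.values[name].to_numpy()
    signal_sd = float(signal.std())
    if snr is not None:
        if not planted_coefs:
            raise ValueError("snr requires planted coefficients")
        noise_sd = signal_sd / snr
    noise = rng.normal(0, noise_sd, len(signal)) if noise_sd > 0 else np.zeros(len(signal))
    log_mbf = intercept + signal + noise
    mbf_by_id = dict(zip(matrix.tf_ids, np.exp(log_mbf)))
    for rec in records:
        rec.mbf = float(mbf_by_id[rec.tf_id])

    truth = GroundTruth(
        stage="cohort",
        params={
            "n": n,
            "planted_coefs": dict(planted_coefs),
            "noise_sd": noise_sd,
            "snr": snr,
            "intercept": intercept,
            "length_range": tuple(length_range),
        },
        seed=seed,
    )
    return SyntheticCohort(
        records=records,
        features=matrix,
        log_mbf=log_mbf,
        planted_coefs=planted_coefs,
        noise_sd=noise_sd,
        signal_sd=signal_sd,
        truth=truth,
    )
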