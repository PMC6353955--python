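"""Single-molecule binding kinetics: spot detection, chromatin-bound event
calling, Hoechst-class assignment, pseudo on-rates and residence times.

Two illumination schemes are used for HaloTag-TF imaging:

* scheme (i): continuous 50-ms-frame movies; captures short binding events
  (a 2-frame event means the molecule stayed put for at least 100 ms).
* scheme (ii): 50-ms TF snapshots alternating with 50-ms Hoechst snapshots,
  550 ms apart, i.e. a 1.2-s cycle; captures long binding events (a
  2-frame event spans at least 1.2 s).

A molecule is called chromatin-bound when consecutive-frame localizations
stay within a 160-nm-diameter region (80-nm radius around the event's
first localization) for at least two frames.  The pseudo on-rate of a
Hoechst intensity class ``a`` is

    psi_on = N_b / (A_a * N_tot * T)

(bound events in the class per unit class area, per detected molecule, per
second of recording), and the residence-time proxy is the scheme-(ii)
bound time averaged over *all* detected molecules,

    tau_res = (1/N_tot) * sum_j t_b,j .
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

#: seconds represented by one additional frame in an event, per scheme
SCHEME_FRAME_S = {"i": 0.05, "ii": 1.2}
#: scheme (ii) cycle structure, seconds: TF 50 ms / wait 550 ms / DNA 50 ms / wait 550 ms
SCHEME_II_CYCLE_S = 0.05 + 0.55 + 0.05 + 0.55

CHROMATIN_CLASSES = ("bright", "intermediate", "dark")


@dataclass
class Detection:
    """One localized molecule in one frame (positions in nm, origin top-left,
    x rightward, y downward)."""

    frame: int
    x: float
    y: float
    intensity: float
    channel: str = "tf"


@dataclass
class BoundEvent:
    molecule_id: int
    start_frame: int
    n_frames: int
    duration: float  # s, scheme-dependent (see event_duration)
    centroid: tuple[float, float]  # nm
    first_loc: tuple[float, float]  # nm, anchor used for class assignment
    chrom_class: str = "unassigned"


@dataclass
class KineticsSummary:
    scheme: str
    n_tot: int
    t_recording: float  # s
    class_counts: dict[str, int] = field(default_factory=dict)  # N_b per class
    class_areas: dict[str, float] = field(default_factory=dict)  # um^2
    psi_on: dict[str, float] = field(default_factory=dict)  # um^-2 s^-1
    tau_res: float = 0.0  # s


def event_duration(n_frames: int, scheme: str) -> float:
    """Bound time implied by an ``n_frames``-frame event under a scheme.

    Scheme (i) frames are contiguous 50-ms exposures, so the molecule was
    bound for the full integration span ``n_frames * 50 ms``.  Scheme (ii)
    frames are instantaneous snapshots 1.2 s apart, so the event spans
    ``(n_frames - 1) * 1.2 s`` between its first and last detection.  The
    minimal 2-frame events therefore last 100 ms and 1.2 s respectively.
    """
    if scheme not in SCHEME_FRAME_S:
        raise ValueError(f"unknown illumination scheme {scheme!r}")
    if scheme == "i":
        return n_frames * SCHEME_FRAME_S["i"]
    return (n_frames - 1) * SCHEME_FRAME_S["ii"]


def _gauss2d(params, xx, yy):
    amp, x0, y0, sigma, off = params
    return off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


def detect_spots(
    frame_image: np.ndarray,
    bg_level: float,
    min_snr: float = 5.0,
    pixel_size_um: float = 0.05,
    psf_sigma_px: float = 1.3,
    frame: int = 0,
    channel: str = "tf",
) -> list[Detection]:
    """Detect diffraction-limited spots and refine positions by 2D Gaussian fit.

    Candidates are local maxima exceeding ``bg_level + min_snr * noise``
    (noise estimated robustly from the median absolute deviation).  Each
    candidate is refined in a 7x7 window by least squares; candidates whose
    fit diverges or wanders out of the window are dropped.  Positions are
    returned in nm.
    """
    img = np.asarray(frame_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    noise = 1.4826 * np.median(np.abs(img - np.median(img)))
    thresh = bg_level + min_snr * max(noise, 1e-12)
    peaks = peak_local_max(img, min_distance=2, threshold_abs=thresh)
    half = 3
    out: list[Detection] = []
    for r, c in peaks:
        r0, r1 = max(r - half, 0), min(r + half + 1, img.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, img.shape[1])
        win = img[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        p0 = [img[r, c] - bg_level, c, r, psf_sigma_px, bg_level]
        try:
            res = least_squares(
                lambda p: (_gauss2d(p, xx, yy) - win).ravel(), p0, max_nfev=500
            )
        except Exception:
            continue
        amp, x0, y0, sigma, _ = res.x
        if not res.success or amp <= 0:
            continue
        if abs(x0 - c) > half or abs(y0 - r) > half:
            continue
        nm = pixel_size_um * 1000.0
        out.append(Detection(frame=frame, x=x0 * nm, y=y0 * nm, intensity=float(amp), channel=channel))
    return out


def link_molecules(locs: pd.DataFrame, max_gap_nm: float = 500.0) -> pd.DataFrame:
    """Nearest-neighbour frame-to-frame linking within a distance gate.

    Adds/overwrites a ``molecule_id`` column.  Matching between consecutive
    frames is greedy on ascending pair distance; unmatched localizations
    start new molecules.
    """
    locs = locs.sort_values(["frame", "x", "y"]).reset_index(drop=True)
    mol = np.full(len(locs), -1, dtype=int)
    next_id = 0
    prev_idx: np.ndarray | None = None
    frames = locs["frame"].to_numpy()
    xy = locs[["x", "y"]].to_numpy(dtype=float)
    for f in np.unique(frames):
        cur = np.flatnonzero(frames == f)
        if prev_idx is not None and frames[prev_idx[0]] == f - 1:
            tree = cKDTree(xy[prev_idx])
            dists, nn = tree.query(xy[cur], distance_upper_bound=max_gap_nm)
            order = np.argsort(dists)
            used: set[int] = set()
            for k in order:
                if not np.isfinite(dists[k]) or nn[k] in used:
                    continue
                mol[cur[k]] = mol[prev_idx[nn[k]]]
                used.add(int(nn[k]))
        for i in cur:
            if mol[i] < 0:
                mol[i] = next_id
                next_id += 1
        prev_idx = cur
    locs = locs.copy()
    locs["molecule_id"] = mol
    return locs


def call_bound_events(
    locs: pd.DataFrame,
    radius_nm: float = 80.0,
    min_frames: int = 2,
    scheme: str = "i",
    anchor: str = "centroid",
) -> list[BoundEvent]:
    """Call chromatin-bound events from per-molecule localization tracks.

    An event is a maximal run of consecutive-frame localizations confined
    to a disc of radius ``radius_nm`` (default 80 nm, i.e. a 160-nm
    diameter).  With ``anchor="centroid"`` (default) the window grows
    while every member stays within ``radius_nm`` of the current window
    centroid — the disc is wherever the detections put it, so two
    localizations up to ``2*radius_nm`` apart still qualify.  With
    ``anchor="first"`` the disc is pinned on the event's first
    localization.  A frame gap terminates a candidate event.  ``locs``
    must contain columns ``molecule_id``, ``frame``, ``x``, ``y``
    (positions in nm) and be sorted by frame within each molecule.
    """
    if anchor not in ("first", "centroid"):
        raise ValueError("anchor must be 'first' or 'centroid'")
    events: list[BoundEvent] = []
    for mid, g in locs.groupby("molecule_id", sort=True):
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) < 0):
            raise ValueError("localizations must be sorted by frame within a molecule")
        if np.any(np.diff(frames) == 0):
            raise ValueError("duplicate frame for one molecule")
        xy = g[["x", "y"]].to_numpy(dtype=float)
        n = len(g)
        i = 0
        while i < n:
            j = i + 1
            while j < n and frames[j] == frames[j - 1] + 1:
                if anchor == "first":
                    fits = np.hypot(*(xy[j] - xy[i])) <= radius_nm
                else:
                    window = xy[i : j + 1]
                    cen = window.mean(axis=0)
                    fits = np.hypot(*(window - cen).T).max() <= radius_nm
                if not fits:
                    break
                j += 1
            if j - i >= min_frames:
                events.append(
                    BoundEvent(
                        molecule_id=int(mid),
                        start_frame=int(frames[i]),
                        n_frames=int(j - i),
                        duration=event_duration(int(j - i), scheme),
                        centroid=tuple(xy[i:j].mean(axis=0)),
                        first_loc=tuple(xy[i]),
                    )
                )
                i = j
            else:
                i += 1
    return events


def classify_chromatin(
    hoechst_image: np.ndarray,
    nucleus_mask: np.ndarray,
    thresholds: tuple[float, float],
    pixel_size_um: float = 0.05,
) -> tuple[np.ndarray, dict[str, float]]:
    """Partition nuclear pixels into bright/intermediate/dark Hoechst classes.

    ``thresholds = (t_low, t_high)`` split the intensity range: dark
    < t_low <= intermediate <= t_high < bright.  Returns a label map
    (0 outside the nucleus, 1 dark, 2 intermediate, 3 bright) and the
    per-class areas in um^2.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds must be strictly ordered")
    img = np.asarray(hoechst_image, dtype=float)
    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[nucleus_mask & (img < t_low)] = 1
    labels[nucleus_mask & (img >= t_low) & (img <= t_high)] = 2
    labels[nucleus_mask & (img > t_high)] = 3
    px_area = pixel_size_um**2
    areas = {
        "dark": float((labels == 1).sum() * px_area),
        "intermediate": float((labels == 2).sum() * px_area),
        "bright": float((labels == 3).sum() * px_area),
    }
    return labels, areas


def assign_events(
    events: list[BoundEvent],
    class_maps: dict[int, np.ndarray],
    pixel_size_um: float = 0.05,
) -> list[BoundEvent]:
    """Assign each event the Hoechst class at its first localization.

    ``class_maps`` maps DNA-snapshot frame indices to label maps (values as
    in :func:`classify_chromatin`).  The most recent DNA frame at or before
    the event's start frame is used, accounting for cell movement during
    long scheme-(ii) acquisitions; events with no preceding DNA frame or a
    position outside the nucleus are left ``"unassigned"``.
    """
    dna_frames = np.array(sorted(class_maps))
    names = {1: "dark", 2: "intermediate", 3: "bright"}
    nm_per_px = pixel_size_um * 1000.0
    for ev in events:
        idx = np.searchsorted(dna_frames, ev.start_frame, side="right") - 1
        if idx < 0:
            ev.chrom_class = "unassigned"
            continue
        cmap = class_maps[int(dna_frames[idx])]
        col = int(round(ev.first_loc[0] / nm_per_px))
        row = int(round(ev.first_loc[1] / nm_per_px))
        if not (0 <= row < cmap.shape[0] and 0 <= col < cmap.shape[1]):
            ev.chrom_class = "unassigned"
            continue
        ev.chrom_class = names.get(int(cmap[row, col]), "unassigned")
    return events


def psi_on_rate(n_b: int, area_um2: float, n_tot: int, t_s: float) -> float:
    """Pseudo on-rate psi_on = N_b / (A_a * N_tot * T) in um^-2 s^-1."""
    if area_um2 <= 0 or n_tot <= 0 or t_s <= 0:
        raise ValueError("area, molecule count and recording time must be positive")
    return n_b / (area_um2 * n_tot * t_s)


def residence_time(
    bound_time_by_molecule, n_tot: int, denominator: str = "all"
) -> float:
    """Residence-time proxy: mean bound time per molecule.

    ``bound_time_by_molecule`` holds each molecule's *total* scheme-(ii)
    bound time (s); molecules with no bound event contribute zero.  With
    ``denominator="all"`` (as written in the defining sum) the divisor is
    ``n_tot``, the total number of detected molecules; ``"bound"`` divides
    by the number of molecules with nonzero bound time instead.
    """
    times = np.asarray(list(bound_time_by_molecule), dtype=float)
    if n_tot <= 0:
        raise ValueError("n_tot must be positive")
    n_bound = int((times > 0).sum())
    if n_bound > n_tot:
        raise ValueError("more bound molecules than detected molecules")
    if denominator == "all":
        return float(times.sum() / n_tot)
    if denominator == "bound":
        return float(times.sum() / n_bound) if n_bound else 0.0
    raise ValueError("denominator must be 'all' or 'bound'")


def summarize_kinetics(
    events: list[BoundEvent],
    n_tot: int,
    class_areas: dict[str, float],
    t_recording: float,
    scheme: str,
) -> KineticsSummary:
    """Per-class event counts, pseudo on-rates and the residence-time proxy."""
    counts = {c: 0 for c in CHROMATIN_CLASSES}
    for ev in events:
        if ev.chrom_class in counts:
            counts[ev.chrom_class] += 1
    psi = {
        c: psi_on_rate(counts[c], class_areas[c], n_tot, t_recording)
        for c in CHROMATIN_CLASSES
        if class_areas.get(c, 0) > 0
    }
    per_mol: dict[int, float] = {}
    for ev in events:
        per_mol[ev.molecule_id] = per_mol.get(ev.molecule_id, 0.0) + ev.duration
    tau = residence_time(per_mol.values(), n_tot) if scheme == "ii" else 0.0
    return KineticsSummary(
        scheme=scheme,
        n_tot=n_tot,
        t_recording=t_recording,
        class_counts=counts,
        class_areas=dict(class_areas),
        psi_on=psi,
        tau_res=tau,
    )
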