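"""Reference-free translational 2D class averaging of boxed granule images.

Mirrors the EM single-particle workflow applied to granule particles picked
from lattice-plane slab projections: box the particles, classify them by
principal-component projection + k-means, then iterate translational-only
alignment to the class averages with reassignment by correlation.  Rotational
alignment is deliberately absent — keeping particle orientations fixed is
what preserves the linker angles on the class averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ParticleStack",
    "ClassSet",
    "LinkerAngles",
    "box_particles",
    "classify_iterate",
    "measure_linker_angles",
]


@dataclass
class ParticleStack:
    """Square particle images of uniform box size, zero mean / unit variance."""

    images: np.ndarray  # (n, box, box)
    pixel_size: float  # nm
    picks: np.ndarray  # (n, 2) (row, col) pick coordinates in the source image
    source: str = ""  # slab descriptor, free text

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("particle stack must be (n, box, box)")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box(self) -> int:
        return self.images.shape[1]


def _normalize(img: np.ndarray) -> np.ndarray:
    img = img - img.mean()
    sd = img.std()
    return img / sd if sd > 0 else img


def box_particles(
    image: np.ndarray,
    picks: Sequence,
    box_px: int,
    pixel_size: float = 1.1,
    source: str = "",
) -> ParticleStack:
    """Crop ``box_px`` x ``box_px`` windows centred on ``picks`` (row, col).

    Picks closer than half a box to the image border are skipped with a
    warning; duplicate picks yield duplicate images (no deduplication).
    """
    import warnings

    image = np.asarray(image, dtype=np.float32)
    half = box_px // 2
    crops, kept = [], []
    for r, c in np.atleast_2d(np.asarray(picks, dtype=int)):
        r0, c0 = r - half, c - half
        if r0 < 0 or c0 < 0 or r0 + box_px > image.shape[0] or c0 + box_px > image.shape[1]:
            warnings.warn(f"pick ({r}, {c}) too close to border, skipped", stacklevel=2)
            continue
        crops.append(_normalize(image[r0 : r0 + box_px, c0 : c0 + box_px]))
        kept.append((r, c))
    if not crops:
        raise ValueError("no picks survived boxing")
    return ParticleStack(np.stack(crops), pixel_size, np.asarray(kept), source)


@dataclass
class ClassSet:
    """Iterative classification result."""

    assignments: np.ndarray  # (n,) class index per particle
    shifts: np.ndarray  # (n, 2) integer (row, col) shifts applied
    averages: np.ndarray  # (k, box, box), zero mean / unit variance
    trace: np.ndarray  # (iterations, n) assignment history
    k: int
    iterations: int


def _shift_int(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape
    rs0, rs1 = max(0, dr), min(h, h + dr)
    cs0, cs1 = max(0, dc), min(w, w + dc)
    out[rs0:rs1, cs0:cs1] = img[rs0 - dr : rs1 - dr, cs0 - dc : cs1 - dc]
    return out


def _best_shift(img: np.ndarray, ref: np.ndarray, max_shift: int):
    """Integer-pixel shift of ``img`` maximizing cross-correlation with ref."""
    f1 = np.fft.rfft2(ref)
    f2 = np.fft.rfft2(img)
    cc = np.fft.irfft2(f1 * np.conj(f2), s=ref.shape)
    cc = np.fft.fftshift(cc)
    ctr = np.array(ref.shape) // 2
    win = cc[
        ctr[0] - max_shift : ctr[0] + max_shift + 1,
        ctr[1] - max_shift : ctr[1] + max_shift + 1,
    ]
    idx = np.unravel_index(np.argmax(win), win.shape)
    dr = idx[0] - max_shift
    dc = idx[1] - max_shift
    return int(dr), int(dc), float(win[idx])


def classify_iterate(
    stack: ParticleStack,
    k: int = 3,
    iterations: int = 8,
    seed: Optional[int] = None,
) -> ClassSet:
    """MSA-style reference-free classification with translational alignment.

    Initial classes come from k-means on the leading principal components of
    the unaligned images.  Each iteration then (1) aligns every particle to
    its class average by integer-pixel cross-correlation (search range
    +-box/4), (2) reassigns each particle to the best-correlating class and
    (3) recomputes the averages.  An emptied class is re-seeded from the
    particle correlating worst with its own class.  Bit-reproducible for a
    fixed ``seed``.
    """
    n = len(stack)
    if n < k:
        raise ValueError(f"need at least k={k} particles, got {n}")
    imgs = stack.images.astype(np.float64)
    box = stack.box
    max_shift = box // 4

    flat = imgs.reshape(n, -1)
    n_comp = min(10, n - 1, flat.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(flat)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs)
    assign = km.labels_.astype(int)

    shifts = np.zeros((n, 2), dtype=int)
    trace = np.zeros((iterations, n), dtype=int)
    averages = _class_means(imgs, assign, shifts, k)

    for it in range(iterations):
        corr = np.zeros((n, k))
        new_shifts = np.zeros((n, 2), dtype=int)
        for i in range(n):
            dr, dc, _ = _best_shift(imgs[i], averages[assign[i]], max_shift)
            aligned = _shift_int(imgs[i], dr, dc)
            for c in range(k):
                corr[i, c] = float((aligned * averages[c]).mean())
            new_shifts[i] = (dr, dc)
        assign = np.argmax(corr, axis=1).astype(int)
        shifts = new_shifts
        # Re-seed empty classes from the worst-fitting particle.
        for c in range(k):
            if not np.any(assign == c):
                own = corr[np.arange(n), assign]
                worst = int(np.argmin(own))
                assign[worst] = c
        averages = _class_means(imgs, assign, shifts, k)
        trace[it] = assign

    return ClassSet(
        assignments=assign,
        shifts=shifts,
        averages=averages.astype(np.float32),
        trace=trace,
        k=k,
        iterations=iterations,
    )


def _class_means(imgs: np.ndarray, assign: np.ndarray, shifts: np.ndarray, k: int):
    box = imgs.shape[1]
    out = np.zeros((k, box, box))
    for c in range(k):
        members = np.where(assign == c)[0]
        if len(members) == 0:
            continue
        acc = np.zeros((box, box))
        for i in members:
            acc += _shift_int(imgs[i], shifts[i, 0], shifts[i, 1])
        out[c] = _normalize(acc / len(members))
    return out


@dataclass
class LinkerAngles:
    """Linker geometry measured on one class average."""

    directions: np.ndarray  # peak azimuths in [0, 360), strongest first
    orientations: np.ndarray  # antipodal-merged directions in [0, 180)
    primary_angle: float  # angle between the two strongest orientations
    has_antipodal: np.ndarray  # per orientation: linker present on both sides
    profile: np.ndarray = field(repr=False, default=None)


def measure_linker_angles(
    avg: np.ndarray,
    granule_radius_px: float,
    spacing_px: float,
    prominence: float = 0.15,
    n_theta: int = 360,
) -> LinkerAngles:
    """Detect linker directions from the annular intensity profile.

    Averages intensity over an annulus between the granule edge and half the
    lattice spacing, as a function of azimuth; peaks above ``prominence``
    (relative to the profile's dynamic range) are linker directions.
    Antipodal peaks (180 deg apart within 10 deg) merge into undirected
    orientations; ``primary_angle`` is the separation of the two strongest
    orientations (the quantity conserved under translational averaging).
    """
    avg = np.asarray(avg, dtype=float)
    ctr = (np.array(avg.shape) - 1) / 2.0
    pk = np.unravel_index(np.argmax(avg), avg.shape)
    if np.linalg.norm(np.array(pk) - ctr) > max(2.0, 0.1 * avg.shape[0]):
        raise ValueError("class average has no central granule")
    # Sub-pixel re-centring on the granule's intensity centroid: a fraction
    # of a pixel of decentring shears the annular azimuths by several degrees.
    # Iterated so the centroid window itself is centred (a window anchored on
    # the argmax corner of a flat-topped granule biases the estimate).
    rr, cc = np.mgrid[: avg.shape[0], : avg.shape[1]]
    est = np.array(pk, dtype=float)
    for _ in range(3):
        disk = (rr - est[0]) ** 2 + (cc - est[1]) ** 2 <= granule_radius_px**2
        w = np.clip(avg - np.median(avg), 0, None) * disk
        if w.sum() <= 0:
            break
        est = np.array([(w * rr).sum(), (w * cc).sum()]) / w.sum()
    ctr = est

    r0 = granule_radius_px
    r1 = max(spacing_px / 2.0, r0 + 1.0)
    radii = np.linspace(r0, r1, max(3, int(r1 - r0) + 1))
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rows = ctr[0] + radii[:, None] * np.sin(theta)[None, :]
    cols = ctr[1] + radii[:, None] * np.cos(theta)[None, :]
    samples = ndimage.map_coordinates(avg, [rows, cols], order=1, cval=0.0)
    profile = samples.mean(axis=0)

    # Circular smoothing (sigma ~2 deg) suppresses plateau jitter from
    # flat-topped linker ridges before peak finding.
    sigma = 2.0 * n_theta / 360.0
    kernel = np.exp(-0.5 * ((np.arange(n_theta) - n_theta // 2) / sigma) ** 2)
    kernel /= kernel.sum()
    smooth = np.real(
        np.fft.ifft(np.fft.fft(profile) * np.fft.fft(np.fft.ifftshift(kernel)))
    )

    rng_prof = smooth.max() - smooth.min()
    dyn = avg.max() - avg.min()
    if rng_prof <= 0 or (dyn > 0 and rng_prof < 0.05 * dyn):
        # profile flat relative to the image contrast: no linkers
        return LinkerAngles(np.empty(0), np.empty(0), np.nan, np.empty(0, bool), profile)
    ext = np.concatenate([smooth, smooth, smooth])
    peaks, _ = find_peaks(ext, prominence=prominence * rng_prof)
    peaks_c = peaks[(peaks >= n_theta) & (peaks < 2 * n_theta)] - n_theta
    if len(peaks_c) == 0:
        return LinkerAngles(np.empty(0), np.empty(0), np.nan, np.empty(0, bool), profile)
    heights = smooth[peaks_c]
    order = np.argsort(-heights)
    # Sub-sample peak refinement: intensity-weighted circular centroid over a
    # +-8 deg window above the local base level.
    directions = []
    half_win = int(round(8.0 * n_theta / 360.0))
    for p in peaks_c[order]:
        idx = (p + np.arange(-half_win, half_win + 1)) % n_theta
        w = smooth[idx] - smooth[idx].min()
        ang = theta[p] + np.radians(np.arange(-half_win, half_win + 1) * 360.0 / n_theta)
        mean = np.angle(np.sum(w * np.exp(1j * ang)) / max(w.sum(), 1e-12))
        directions.append(np.degrees(mean) % 360.0)
    directions = np.asarray(directions)

    orientations, has_anti = [], []
    used = np.zeros(len(directions), dtype=bool)
    for i, d in enumerate(directions):
        if used[i]:
            continue
        partner = None
        for j in range(i + 1, len(directions)):
            if used[j]:
                continue
            dd = abs((directions[j] - d + 180.0) % 360.0 - 180.0)
            if dd > 170.0:
                partner = j
                break
        orientations.append(d % 180.0)
        has_anti.append(partner is not None)
        used[i] = True
        if partner is not None:
            used[partner] = True

    orientations = np.asarray(orientations)
    if len(orientations) >= 2:
        diff = abs(orientations[0] - orientations[1])
        primary = min(diff, 180.0 - diff)
    else:
        primary = np.nan
    return LinkerAngles(
        directions=directions,
        orientations=orientations,
        primary_angle=float(primary),
        has_antipodal=np.asarray(has_anti, dtype=bool),
        profile=profile,
    )
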