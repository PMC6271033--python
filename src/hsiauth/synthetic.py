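"""Seeded synthetic SWIR scenes with ground truth.

No public hypercubes of authenticated *Echinacea* powders exist, so every
pipeline stage is exercised on synthetic scenes built from stylized
endmember spectra: Gaussian absorption bands on a sloping baseline, with the
species-discriminating bands concentrated in the 1937-2400 nm combination
region, roots more chemically distinct than leaves, and *E. pallida* the
most distinct species in both organs.  Pixels receive multiplicative scatter
(lognormal), an additive baseline offset and white noise, are converted to
reflectance and then to raw counts against known white/dark references — so
calibration, masking, preprocessing and classification can all be checked
against exact truth.  The endmembers are caricatures; no spectral realism is
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hypercube import Hypercube, ReferencePair, Region, RegionLayout, SignalKind

__all__ = [
    "EndmemberSpec",
    "Well",
    "SceneSpec",
    "Scene",
    "StudyReplica",
    "default_echinacea_library",
    "default_wavelength_grid",
    "render_scene",
    "make_study_replica",
    "SPECIES",
    "EXCIPIENT",
    "STAGE",
]

SPECIES = ("angustifolia", "purpurea", "pallida")
EXCIPIENT = "excipient"
STAGE = "stage"

DEFAULT_SHAPE = (256, 320)
DEFAULT_WELL_RADIUS = 14.0


def default_wavelength_grid(n_bands: int = 256) -> np.ndarray:
    """920-2514 nm on a uniform grid (~6.25 nm spacing at 256 bands)."""
    return np.linspace(920.0, 2514.0, n_bands)


@dataclass(frozen=True)
class EndmemberSpec:
    """Pure-material absorbance spectrum: baseline + Gaussian bands.

    ``bands`` entries are (center nm, width nm, depth in absorbance units).
    ``species`` is the class the material belongs to (None for excipient and
    stage).  ``scatter_sigma`` optionally overrides the scene's multiplicative
    scatter for pixels of this material.
    """

    name: str
    baseline: float
    slope: float  # absorbance change across the full grid span
    bands: tuple[tuple[float, float, float], ...]
    species: str | None = None
    organ: str | None = None
    scatter_sigma: float | None = None

    def spectrum(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        span = wl[-1] - wl[0]
        a = self.baseline + self.slope * (wl - wl[0]) / span
        for center, width, depth in self.bands:
            if width <= 0:
                raise ValueError(f"band width must be positive in {self.name}")
            a = a + depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return a


def default_echinacea_library() -> dict[str, EndmemberSpec]:
    """Six plant endmembers (3 species x root/leaf) + excipient + stage.

    Shared vegetation bands (water/cellulose OH, C-H combinations) are common
    to all plant materials; species identity lives in a few bands between
    1937 and 2400 nm whose depth is larger in roots than leaves.  The
    excipient mimics a stearate filler: strong aliphatic C-H bands, nothing
    at the species-specific positions.  The stage is dark and spectrally
    flat.
    """
    common = ((1450.0, 55.0, 0.12), (1935.0, 65.0, 0.22), (2100.0, 85.0, 0.10),
              (2310.0, 45.0, 0.08))
    organ_bands = {
        "root": ((1580.0, 80.0, 0.06),),
        "leaf": ((1680.0, 70.0, 0.08), (2270.0, 60.0, 0.05)),
    }
    # species-specific band positions; pallida gets an extra band and a depth
    # boost, making it the most distinct species in both organs
    species_bands = {
        "angustifolia": ((1985.0, 28.0, 1.0), (2205.0, 36.0, 0.6)),
        "purpurea": ((2045.0, 28.0, 1.0), (2255.0, 36.0, 0.6)),
        "pallida": ((2135.0, 24.0, 1.4), (2390.0, 30.0, 1.0), (1960.0, 30.0, 0.5)),
    }
    # leaves carry shallower species features than roots; their extra organ
    # bands further dilute the species signal after SNV, so leaf separation
    # comes out weaker than root separation without a second mechanism
    organ_depth = {"root": 0.18, "leaf": 0.13}
    baseline = {"root": 0.35, "leaf": 0.30}

    library: dict[str, EndmemberSpec] = {}
    for sp in SPECIES:
        for organ in ("root", "leaf"):
            depth = organ_depth[organ]
            bands = common + organ_bands[organ] + tuple(
                (c, w, d * depth) for c, w, d in species_bands[sp]
            )
            name = f"{sp}_{organ}"
            library[name] = EndmemberSpec(
                name=name, baseline=baseline[organ], slope=0.10,
                bands=bands, species=sp, organ=organ,
            )
    # non-authentic matrix (processed extract / blended filler): averaged
    # vegetation chemistry with no distinct species signature plus weak
    # processing-induced bands, the spectral profile a concentrate or
    # multi-herb filler presents — a calibrated model predicts it near the
    # class-mean dummy values, outside every cut-off window
    exc_bands = list(common)
    for bands in organ_bands.values():
        exc_bands.extend((c, w, d * 0.5) for c, w, d in bands)
    mean_depth = (organ_depth["root"] + organ_depth["leaf"]) / 2.0
    for bands in species_bands.values():
        exc_bands.extend((c, w, d * mean_depth / 3.0) for c, w, d in bands)
    exc_bands += [(1730.0, 30.0, 0.04), (1250.0, 50.0, 0.04)]
    library[EXCIPIENT] = EndmemberSpec(
        name=EXCIPIENT, baseline=0.325, slope=0.10, bands=tuple(exc_bands),
    )
    library[STAGE] = EndmemberSpec(name=STAGE, baseline=0.04, slope=0.02, bands=())
    return library


# ---------------------------------------------------------------------------
# scene specification


@dataclass(frozen=True)
class Well:
    """A disk of material on the stage.

    ``material`` is an endmember name or a {endmember: weight} mixture with
    non-negative weights summing to <= 1; any remainder is excipient.
    ``mixing="segregated"`` (default) draws each pixel's component from the
    weights — a powder blend whose particles are larger than a pixel;
    ``mixing="intimate"`` mixes the weighted spectra within every pixel.
    """

    label: str
    cy: float
    cx: float
    radius: float
    material: "str | dict[str, float]"
    class_hint: str | None = None
    mixing: str = "segregated"

    def weights(self) -> dict[str, float]:
        if isinstance(self.material, str):
            return {self.material: 1.0}
        w = {k: float(v) for k, v in self.material.items()}
        if any(v < 0 for v in w.values()):
            raise ValueError(f"negative mixture weight in well {self.label!r}")
        total = sum(w.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"mixture weights in well {self.label!r} sum to {total} > 1")
        if total < 1.0 - 1e-9:
            w[EXCIPIENT] = w.get(EXCIPIENT, 0.0) + (1.0 - total)
        return w

    def region(self) -> Region:
        return Region(self.label, "disk", (self.cy, self.cx, self.radius), self.class_hint)


@dataclass
class SceneSpec:
    shape: tuple[int, int] = DEFAULT_SHAPE
    wavelengths_nm: np.ndarray = field(default_factory=default_wavelength_grid)
    wells: list[Well] = field(default_factory=list)
    scatter_sigma: float = 0.06  # lognormal sigma of the per-pixel gain
    offset_sigma: float = 0.015  # additive baseline offset, absorbance units
    noise_sigma: float = 0.004  # white noise per band, absorbance units
    seed: int = 0

    def __post_init__(self) -> None:
        for i, a in enumerate(self.wells):
            for b in self.wells[i + 1 :]:
                d = np.hypot(a.cy - b.cy, a.cx - b.cx)
                if d < a.radius + b.radius:
                    raise ValueError(f"wells {a.label!r} and {b.label!r} overlap")


@dataclass
class Scene:
    """A rendered scene: raw cube, references, and full ground truth."""

    raw: Hypercube
    refs: ReferencePair
    layout: RegionLayout
    truth_map: np.ndarray  # per-pixel material class: species key, excipient or stage
    sample_mask: np.ndarray  # True where a well covers the pixel
    composition: pd.DataFrame  # per-well true weights per species + excipient


def _reference_vectors(wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    wl = np.asarray(wavelengths_nm, dtype=float)
    rel = (wl - wl[0]) / (wl[-1] - wl[0])
    white = 3000.0 + 800.0 * np.sin(np.pi * rel)
    dark = np.full_like(wl, 120.0)
    return dark, white


def render_scene(spec: SceneSpec, library: dict[str, EndmemberSpec] | None = None) -> Scene:
    """Render a scene spec to raw counts with known references and truth.

    Pixel absorbance: a = m * sum_i w_i * e_i(lambda) + offset + eps, with
    m lognormal, offset and eps Gaussian, all drawn from the scene seed; the
    cube is converted to reflectance 10^-a and then to counts against the
    synthetic references.  Identical seeds give bit-identical scenes.
    """
    library = library or default_echinacea_library()
    ny, nx = spec.shape
    wl = np.asarray(spec.wavelengths_nm, dtype=float)
    nb = len(wl)
    rng = np.random.default_rng(spec.seed)

    names = sorted(library)
    spectra = np.stack([library[n].spectrum(wl) for n in names])  # (k, nb)
    name_idx = {n: i for i, n in enumerate(names)}

    npx = ny * nx
    weight_mat = np.zeros((npx, len(names)))
    weight_mat[:, name_idx[STAGE]] = 1.0
    truth = np.full((ny, nx), STAGE, dtype=object)
    sample_mask = np.zeros((ny, nx), dtype=bool)
    scatter_override = np.full(npx, np.nan)

    comp_rows = []
    for well in spec.wells:
        inside = well.region().member_mask((ny, nx))
        if not inside.any():
            raise ValueError(f"well {well.label!r} lies outside the image")
        flat = np.flatnonzero(inside.reshape(-1))
        w = well.weights()
        for name in w:
            if name not in library:
                raise KeyError(f"well {well.label!r} references unknown endmember {name!r}")
        weight_mat[flat] = 0.0
        if well.mixing == "segregated" and len(w) > 1:
            comps = list(w)
            probs = np.array([w[c] for c in comps])
            draw = rng.choice(len(comps), size=len(flat), p=probs / probs.sum())
            for ci, comp in enumerate(comps):
                weight_mat[flat[draw == ci], name_idx[comp]] = 1.0
            pix_names = np.array(comps, dtype=object)[draw]
        else:
            for comp, val in w.items():
                weight_mat[flat, name_idx[comp]] = val
            dominant = max(w, key=w.get)
            pix_names = np.full(len(flat), dominant, dtype=object)
        yy, xx = np.unravel_index(flat, (ny, nx))
        truth[yy, xx] = [
            library[n].species or (EXCIPIENT if n == EXCIPIENT else n) for n in pix_names
        ]
        sample_mask[yy, xx] = True
        for name in w:
            scat = library[name].scatter_sigma
            if scat is not None:
                scatter_override[flat] = scat
        comp = {"well": well.label, "claim": well.class_hint or ""}
        for sp in SPECIES:
            comp[sp] = sum(v for n, v in w.items() if library[n].species == sp)
        comp[EXCIPIENT] = w.get(EXCIPIENT, 0.0)
        comp_rows.append(comp)

    absorbance = weight_mat @ spectra  # (npx, nb)
    m = np.exp(rng.normal(0.0, spec.scatter_sigma, size=npx))
    override = np.isfinite(scatter_override)
    if override.any():
        m[override] = np.exp(rng.normal(0.0, 1.0, size=int(override.sum()))
                             * scatter_override[override])
    offset = rng.normal(0.0, spec.offset_sigma, size=npx)
    absorbance = absorbance * m[:, None] + offset[:, None]
    if spec.noise_sigma > 0:
        absorbance += rng.normal(0.0, spec.noise_sigma, size=absorbance.shape)

    refl = np.power(10.0, -absorbance)
    dark, white = _reference_vectors(wl)
    counts = dark + refl * (white - dark)
    raw = Hypercube(counts.reshape(ny, nx, nb), wl, SignalKind.RAW_COUNTS,
                    {"description": "synthetic scene"})

    ref_shape = (8, nx, nb)
    dark_cube = Hypercube(np.broadcast_to(dark, ref_shape).copy(), wl, SignalKind.RAW_COUNTS)
    white_cube = Hypercube(np.broadcast_to(white, ref_shape).copy(), wl, SignalKind.RAW_COUNTS)

    layout = RegionLayout([w.region() for w in spec.wells])
    cols = ["well", "claim", *SPECIES, EXCIPIENT]
    composition = pd.DataFrame(comp_rows, columns=cols)
    return Scene(raw, ReferencePair(dark_cube, white_cube), layout, truth, sample_mask,
                 composition)


# ---------------------------------------------------------------------------
# the study replica


@dataclass
class StudyReplica:
    """Two rendered scenes: 18 authentic wells, then 24 product wells."""

    calibration_scene: Scene
    product_scene: Scene


def _grid_centers(n_rows: int, n_cols: int, shape: tuple[int, int],
                  rng: np.random.Generator, radius: float = DEFAULT_WELL_RADIUS,
                  jitter: float = 5.0) -> list[tuple[float, float]]:
    ny, nx = shape
    # keep jittered wells clear of each other whatever the grid density
    jitter = max(0.0, min(jitter, 0.5 * min(ny / n_rows, nx / n_cols) - radius - 1.0))
    ys = np.linspace(0, ny, n_rows + 1)[:-1] + ny / (2 * n_rows)
    xs = np.linspace(0, nx, n_cols + 1)[:-1] + nx / (2 * n_cols)
    centers = []
    for y in ys:
        for x in xs:
            centers.append((float(y + rng.uniform(-jitter, jitter)),
                            float(x + rng.uniform(-jitter, jitter))))
    return centers


_SPECIES_CODE = {"angustifolia": "EA", "purpurea": "EP", "pallida": "EPa"}

# the 20 product wells + 4 authentic controls; weights over endmembers,
# remainder (if any) is excipient.  Claims follow the product labels; a few
# are deliberately wrong, as happens with commercial products.
_PRODUCTS: list[tuple[str, "str | dict[str, float]"]] = [
    ("purpurea+angustifolia", {"purpurea_root": 0.55, "purpurea_leaf": 0.35,
                               "angustifolia_leaf": 0.10}),
    ("angustifolia", {EXCIPIENT: 1.0}),  # extract
    ("purpurea", {"angustifolia_root": 0.88, "purpurea_root": 0.12}),  # mislabeled
    ("purpurea", {EXCIPIENT: 1.0}),  # concentrate
    ("purpurea+angustifolia", {EXCIPIENT: 0.75, "angustifolia_root": 0.15,
                               "purpurea_root": 0.10}),
    ("purpurea+angustifolia", {"angustifolia_root": 0.95, "purpurea_root": 0.05}),
    ("purpurea", {EXCIPIENT: 1.0}),  # extract
    ("purpurea", {EXCIPIENT: 1.0}),  # extract
    ("pallida", {"purpurea_root": 0.75, "pallida_root": 0.08, EXCIPIENT: 0.17}),  # mislabeled
    ("purpurea+angustifolia", {"angustifolia_root": 0.85, "purpurea_root": 0.15}),
    ("angustifolia", "angustifolia_root"),
    ("purpurea", {"purpurea_leaf": 0.75, EXCIPIENT: 0.25}),
    ("pallida+purpurea", {EXCIPIENT: 0.72, "purpurea_root": 0.23, "pallida_root": 0.05}),
    ("purpurea", {"purpurea_root": 0.55, "purpurea_leaf": 0.35, "angustifolia_root": 0.10}),
    ("angustifolia", {EXCIPIENT: 1.0}),  # extract
    ("purpurea", {"angustifolia_root": 0.62, "purpurea_leaf": 0.12, EXCIPIENT: 0.26}),
    ("purpurea", {"purpurea_root": 0.95, EXCIPIENT: 0.05}),
    ("angustifolia+pallida+purpurea", {"purpurea_root": 0.92, "pallida_root": 0.02,
                                       EXCIPIENT: 0.06}),
    ("purpurea", {"purpurea_leaf": 0.88, EXCIPIENT: 0.12}),
    ("multi_herb", {EXCIPIENT: 0.65, "angustifolia_root": 0.16, "purpurea_root": 0.08,
                    "pallida_root": 0.11}),
    # authentic raw-material controls
    ("purpurea", "purpurea_leaf"),
    ("angustifolia", "angustifolia_root"),
    ("purpurea", "purpurea_root"),
    ("angustifolia", "angustifolia_leaf"),
]


def make_study_replica(
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    n_bands: int = 256,
    well_radius: float = DEFAULT_WELL_RADIUS,
    scatter_sigma: float = 0.06,
    offset_sigma: float = 0.015,
    noise_sigma: float = 0.004,
) -> StudyReplica:
    """Render the two study scenes from one seed.

    Scene 1: 18 authentic wells (3 species x 2 organs x 3 replicates) placed
    randomly on a 3x6 grid.  Scene 2: 24 wells — 20 "commercial products"
    (pure species, two-species blends, excipient-only extracts and a
    multi-herb formulation) plus 4 authentic controls.
    """
    rng = np.random.default_rng(seed)
    wl = default_wavelength_grid(n_bands)

    # scene 1 -- authentic raw material
    samples = [(sp, organ, rep) for sp in SPECIES for organ in ("root", "leaf")
               for rep in (1, 2, 3)]
    order = rng.permutation(len(samples))
    centers = _grid_centers(3, 6, shape, rng, radius=well_radius)
    wells1 = []
    for pos, idx in enumerate(order):
        sp, organ, rep = samples[idx]
        cy, cx = centers[pos]
        label = f"{_SPECIES_CODE[sp]}{organ[0].upper()}-{rep}"
        wells1.append(Well(label, cy, cx, well_radius, f"{sp}_{organ}", class_hint=sp))
    spec1 = SceneSpec(shape=shape, wavelengths_nm=wl, wells=wells1,
                      scatter_sigma=scatter_sigma, offset_sigma=offset_sigma,
                      noise_sigma=noise_sigma, seed=int(rng.integers(0, 2**31 - 1)))

    # scene 2 -- products and controls
    centers2 = _grid_centers(4, 6, shape, rng, radius=well_radius)
    wells2 = []
    for i, ((claim, material), (cy, cx)) in enumerate(zip(_PRODUCTS, centers2), start=1):
        label = f"product-{i:02d}" if i <= 20 else f"control-{i:02d}"
        wells2.append(Well(label, cy, cx, well_radius, material, class_hint=claim))
    spec2 = SceneSpec(shape=shape, wavelengths_nm=wl, wells=wells2,
                      scatter_sigma=scatter_sigma, offset_sigma=offset_sigma,
                      noise_sigma=noise_sigma, seed=int(rng.integers(0, 2**31 - 1)))

    return StudyReplica(render_scene(spec1), render_scene(spec2))
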