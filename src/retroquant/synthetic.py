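"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate what the live-cell assay records: adherent cells
with a nucleus and punctate endolysosomes, a GFP reporter that decays in
endolysosomes and accumulates in nuclei after chemical induction of the
protease, a constant nuclear red marker, and a far-red lysosome probe with
mild global drift. Side tables mimic the paper-and-gel readouts: DMM
pulse-chase band intensities, immunogold particle counts per MVB, and
exosome blot densitometry.

Everything is deterministic under a fixed seed, and each generator records
the ground truth (geometry, masks, kinetic parameters, noiseless traces)
needed for recovery tests.

Geometry is 2-D (one focal plane, matching the per-frame 2-D
quantification); organelles are discs and the plasma membrane a thin rim
of the cell disc. Images default to 512x512 (the acquisition scan format)
but any size works.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, PlacementError
from .kinetics import KineticParams, pools_to_frame, simulate_pools

__all__ = [
    "Disc",
    "Cell",
    "CellGeometry",
    "AcquisitionParams",
    "GroundTruth",
    "generate_geometry",
    "generate_timelapse",
    "generate_pulse_chase_table",
    "generate_immunogold_counts",
    "generate_exosome_blot_table",
]


@dataclass(frozen=True)
class Disc:
    row: float
    col: float
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.row) ** 2 + (cc - self.col) ** 2 <= self.radius**2


@dataclass(frozen=True)
class Cell:
    body: Disc
    nucleus: Disc
    endolysosomes: tuple[Disc, ...]


@dataclass(frozen=True)
class CellGeometry:
    """Static 2-D layout of cells, nuclei and endolysosomes."""

    image_shape: tuple[int, int]
    cells: tuple[Cell, ...]
    pm_thickness_px: float = 3.0

    def masks(self) -> dict[str, np.ndarray]:
        """Pairwise-disjoint boolean masks: el, nuc, pm, cyto (plus 'cell' union)."""
        shape = self.image_shape
        cell = np.zeros(shape, dtype=bool)
        interior = np.zeros(shape, dtype=bool)
        nuc = np.zeros(shape, dtype=bool)
        el = np.zeros(shape, dtype=bool)
        for c in self.cells:
            cell |= c.body.mask(shape)
            interior |= Disc(
                c.body.row, c.body.col, c.body.radius - self.pm_thickness_px
            ).mask(shape)
            nuc |= c.nucleus.mask(shape)
            for e in c.endolysosomes:
                el |= e.mask(shape)
        pm = cell & ~interior & ~nuc & ~el
        nuc = nuc & ~el
        cyto = cell & ~pm & ~nuc & ~el
        return {"el": el, "nuc": nuc, "pm": pm, "cyto": cyto, "cell": cell}


def generate_geometry(
    n_cells: int,
    seed: int,
    image_shape: tuple[int, int] = (512, 512),
    cell_radius_range: tuple[float, float] | None = None,
    n_el_range: tuple[int, int] = (8, 15),
    el_radius_range: tuple[float, float] = (2.0, 5.0),
    pm_thickness_px: float = 3.0,
    max_tries: int = 5000,
) -> CellGeometry:
    """Rejection-sample a non-overlapping cell layout; deterministic per seed.

    Nuclei sit strictly inside their cell; endolysosomes sit in the
    cytoplasm (inside the plasma-membrane rim, outside the nucleus) and do
    not overlap each other. Raises :class:`PlacementError` when the retry
    budget is exhausted.
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    if el_radius_range[0] < 2.0:
        raise DomainError("endolysosome radii must be >= 2 px")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if cell_radius_range is None:
        # scale with the field of view, floored so the cytoplasm can still
        # host >= 2 px endolysosomes clear of the nucleus and the PM rim
        m = min(h, w)
        lo = max(24.0, 0.09 * m)
        cell_radius_range = (lo, max(lo + 6.0, 0.12 * m))
    cells: list[Cell] = []
    placed_bodies: list[Disc] = []
    for _ in range(n_cells):
        for attempt in range(max_tries):
            r = rng.uniform(*cell_radius_range)
            row = rng.uniform(r + 1, h - r - 1)
            col = rng.uniform(r + 1, w - r - 1)
            body = Disc(row, col, r)
            if all(
                math.hypot(b.row - row, b.col - col) > b.radius + r + 2
                for b in placed_bodies
            ):
                break
        else:
            raise PlacementError(
                f"could not place cell {len(cells)} within {max_tries} tries"
            )
        nuc_r = 0.35 * r
        ang = rng.uniform(0, 2 * math.pi)
        off = rng.uniform(0, 0.15 * r)
        nucleus = Disc(row + off * math.sin(ang), col + off * math.cos(ang), nuc_r)

        n_el = int(rng.integers(n_el_range[0], n_el_range[1] + 1))
        els: list[Disc] = []
        for _ in range(n_el):
            for attempt in range(max_tries):
                er = rng.uniform(*el_radius_range)
                max_d = r - pm_thickness_px - er - 1
                d = math.sqrt(rng.uniform(0, 1)) * max_d
                a = rng.uniform(0, 2 * math.pi)
                e = Disc(row + d * math.sin(a), col + d * math.cos(a), er)
                far_from_nuc = (
                    math.hypot(e.row - nucleus.row, e.col - nucleus.col)
                    > nuc_r + er + 1
                )
                no_overlap = all(
                    math.hypot(o.row - e.row, o.col - e.col) > o.radius + er + 1
                    for o in els
                )
                if far_from_nuc and no_overlap and d <= max_d:
                    els.append(e)
                    break
            else:
                raise PlacementError(
                    f"could not place endolysosome within {max_tries} tries"
                )
        placed_bodies.append(body)
        cells.append(Cell(body=body, nucleus=nucleus, endolysosomes=tuple(els)))
    return CellGeometry(
        image_shape=image_shape, cells=tuple(cells), pm_thickness_px=pm_thickness_px
    )


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging protocol and camera model.

    Defaults follow the acquisition protocol: one frame every 180 s for
    120 frames (~6 h). Intensities are arbitrary camera units on a uint16
    scale. ``lyso_drift`` is the fractional linear decline of the lysosome
    probe over the movie (exercises threshold interpolation).
    """

    frame_interval_s: float = 180.0
    n_frames: int = 120
    cyto_bg: float = 200.0
    el_gain: float = 2000.0
    pm_gain: float = 1500.0
    nuc_gain: float = 1500.0
    pm_nuc_gain: float = 800.0
    red_nuc: float = 3000.0
    lyso_el: float = 2500.0
    lyso_drift: float = 0.1
    shot_noise: bool = False
    read_noise_sigma: float = 0.0
    bleach_per_min: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bleach_per_min", tuple(self.bleach_per_min))
        if self.frame_interval_s <= 0:
            raise DomainError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise DomainError("n_frames must be >= 2")
        if self.read_noise_sigma < 0:
            raise DomainError("read_noise_sigma must be >= 0")
        if any(b < 0 for b in self.bleach_per_min):
            raise DomainError("photobleaching rates must be >= 0")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0


@dataclass
class GroundTruth:
    """The simulator's record of what it drew: geometry, kinetics, truth traces."""

    geometry: CellGeometry
    kinetics: KineticParams
    acquisition: AcquisitionParams
    masks: dict[str, np.ndarray]
    pools: pd.DataFrame = field(repr=False)
    intensities: pd.DataFrame = field(repr=False)

    def pools_csv(self) -> str:
        return self.pools.to_csv(index=False, float_format="%.12g")

    def intensities_csv(self) -> str:
        return self.intensities.to_csv(index=False, float_format="%.12g")


def generate_timelapse(
    geometry: CellGeometry,
    kinetics: KineticParams,
    acq: AcquisitionParams,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a (T, 3, H, W) uint16 stack (gfp, red, lyso) plus its ground truth.

    Channel semantics: endolysosomal GFP scales with the kinetic observable
    ``L + I_dyn + I_inert`` on top of the constant cytosolic background;
    nuclear GFP rises with ``N_nuc`` plus a surface-derived term (cleaved
    reporter from the plasma membrane also carries the NLS); the PM rim has
    its own pool cleaved at the same ``k_cleave``. The red channel is
    constant in nuclei; the far-red channel is constant per endolysosome up
    to a global linear drift. Noise is applied only after the noiseless
    truth is recorded.
    """
    times = acq.times_min
    states = simulate_pools(kinetics, times)
    pools = pools_to_frame(states)
    obs = pools["EL_observable"].to_numpy()
    pm_pool = np.exp(-kinetics.k_cleave * times)
    nuc_pool = pools["N_nuc"].to_numpy()
    masks = geometry.masks()

    drift = 1.0 - acq.lyso_drift * times / times[-1] if times[-1] > 0 else np.ones_like(times)
    rows = []
    h, w = geometry.image_shape
    stack = np.zeros((acq.n_frames, 3, h, w), dtype=np.uint16)
    rng = np.random.default_rng(acq.rng_seed)
    for i, t in enumerate(times):
        gfp = np.zeros((h, w))
        gfp[masks["cyto"]] = acq.cyto_bg
        gfp[masks["el"]] = acq.cyto_bg + acq.el_gain * obs[i]
        gfp[masks["pm"]] = acq.cyto_bg + acq.pm_gain * pm_pool[i]
        gfp[masks["nuc"]] = (
            acq.nuc_gain * nuc_pool[i] + acq.pm_nuc_gain * (1.0 - pm_pool[i])
        )
        red = np.zeros((h, w))
        red[masks["nuc"]] = acq.red_nuc
        lyso = np.zeros((h, w))
        lyso[masks["el"]] = acq.lyso_el * drift[i]

        rows.append(
            {
                "frame": i,
                "time_min": t,
                "el_gfp": acq.cyto_bg + acq.el_gain * obs[i],
                "cyto_gfp": acq.cyto_bg,
                "nuc_gfp": acq.nuc_gain * nuc_pool[i]
                + acq.pm_nuc_gain * (1.0 - pm_pool[i]),
                "pm_gfp": acq.cyto_bg + acq.pm_gain * pm_pool[i],
                "el_lyso": acq.lyso_el * drift[i],
            }
        )
        for ci, (img, bleach) in enumerate(zip((gfp, red, lyso), acq.bleach_per_min)):
            img = img * math.exp(-bleach * t)
            if acq.shot_noise:
                img = rng.poisson(img).astype(float)
            if acq.read_noise_sigma > 0:
                img = img + rng.normal(0.0, acq.read_noise_sigma, img.shape)
            stack[i, ci] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        geometry=geometry,
        kinetics=kinetics,
        acquisition=acq,
        masks=masks,
        pools=pools,
        intensities=pd.DataFrame(rows),
    )
    return stack, truth


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def generate_pulse_chase_table(
    half_life_h: float,
    times_h: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    initial: float = 1.0,
) -> pd.DataFrame:
    """DMM pulse-chase band intensities: columns ``time_h, mature_band, HM_band``.

    The mature band decays as ``2^(-t/half_life)``; the high-mannose (HM)
    band of newly synthesized reporter grows as ``1 - 2^(-t/half_life)``
    (synthesis balancing degradation, so total protein is homeostatic).
    Multiplicative mean-one lognormal noise with CV ``noise_cv``.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    if half_life_h <= 0:
        raise DomainError("half_life_h must be > 0")
    t = np.asarray(times_h, dtype=float)
    if t.size < 1 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise DomainError("times_h must be sorted and start at 0")
    rng = np.random.default_rng(seed)
    decay = 2.0 ** (-t / half_life_h)
    mature = initial * decay * _lognormal_factors(rng, noise_cv, t.size)
    hm = initial * (1.0 - decay) * _lognormal_factors(rng, noise_cv, t.size)
    return pd.DataFrame({"time_h": t, "mature_band": mature, "HM_band": hm})


def generate_immunogold_counts(
    rho: float,
    n_mvb: int,
    mean_total: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Immunogold particle counts per MVB: columns ``mvb_id, gold_ilv, gold_lm``.

    Total particles per MVB are Poisson(``mean_total``); each lands on an
    ILV with probability ``rho/(1+rho)``, else on the limiting membrane.
    """
    if not np.isfinite(rho) or rho < 0:
        raise DomainError("rho must be finite and >= 0")
    if n_mvb < 1:
        raise DomainError("n_mvb must be >= 1")
    if mean_total <= 0:
        raise DomainError("mean_total must be > 0")
    rng = np.random.default_rng(seed)
    total = rng.poisson(mean_total, size=n_mvb)
    p = rho / (1.0 + rho)
    ilv = rng.binomial(total, p)
    return pd.DataFrame(
        {"mvb_id": np.arange(n_mvb), "gold_ilv": ilv, "gold_lm": total - ilv}
    )


def generate_exosome_blot_table(
    true_gfp_over_cd63: Mapping[str, float],
    noise_cv: float = 0.0,
    n_replicates: int = 6,
    seed: int = 0,
    include_ifitm3: bool = False,
    base_signal: float = 1.0,
) -> pd.DataFrame:
    """Exosome blot densitometry: ``condition, replicate, gfp_signal, cd63_signal``
    (plus ``ifitm3_signal`` when requested).

    Normalizer signals get independent mean-one lognormal noise; the GFP
    signal is the true ratio times the geometric mean of the generated
    normalizer signals times its own noise, so the per-replicate ratio
    estimator is unbiased for the specified truth at any CV.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    if any(r <= 0 for r in true_gfp_over_cd63.values()):
        raise DomainError("true ratios must be > 0")
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for cond, ratio in true_gfp_over_cd63.items():
        cd63 = base_signal * _lognormal_factors(rng, noise_cv, n_replicates)
        norm = cd63.copy()
        if include_ifitm3:
            ifitm3 = base_signal * _lognormal_factors(rng, noise_cv, n_replicates)
            norm = np.sqrt(cd63 * ifitm3)
        gfp = ratio * norm * _lognormal_factors(rng, noise_cv, n_replicates)
        for rep in range(n_replicates):
            rec = {
                "condition": cond,
                "replicate": rep,
                "gfp_signal": gfp[rep],
                "cd63_signal": cd63[rep],
            }
            if include_ifitm3:
                rec["ifitm3_signal"] = ifitm3[rep]
            records.append(rec)
    return pd.DataFrame.from_records(records)
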