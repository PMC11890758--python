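"""Seeded synthetic screen generators with known ground truth.

The raw screens behind this calculus are plate-reader exports that are
not publicly deposited, so every pipeline stage is exercised against
simulated plates whose generating parameters are known exactly:

* a BRET saturation screen — per-gene acceptor/donor titration series
  drawn from the hyperbolic saturation model plus additive Gaussian
  noise, with planted true interactors, two empty-vector control series
  and donor-only baseline wells;
* an immune co-culture (HTiP) screen — paired -PBMC/+PBMC viability
  plates with multiplicative lognormal assay noise and planted
  immune-dependent killers of known selectivity;
* 4PL dose-response tables with multiplicative Gaussian noise.

All generators are pure functions of their spec (seed included):
repeated calls return identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .htip import four_pl
from .plate_io import GEOMETRIES
from .saturation import saturation_model

DEFAULT_X_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

#: construct labels the generators use for the control series
CTRL1_CONSTRUCT = "empty-nluc"     # empty donor vector + Venus prey
CTRL2_CONSTRUCT = "empty-venus"    # NLuc bait + empty acceptor vector
BASELINE_CONSTRUCT = "donor-baseline"  # NLuc alone, no acceptor plasmid


def _well_id(index: int, geometry: int) -> tuple[int, str]:
    """(plate_number, canonical well) for a running well index."""
    n_rows, n_cols = GEOMETRIES[geometry]
    per_plate = n_rows * n_cols
    plate, offset = divmod(index, per_plate)
    row, col = divmod(offset, n_cols)
    letters = chr(ord("A") + row) if row < 26 else "A" + chr(ord("A") + row - 26)
    return plate + 1, f"{letters}{col + 1:02d}"


# ---------------------------------------------------------------------------
# BRET saturation screen
# ---------------------------------------------------------------------------

@dataclass
class BretScreenTruth:
    """Generating conditions for a synthetic BRET PPI screen.

    ``bmax_hit`` is the uniform range of the saturation plateau for true
    interactors; non-interactors and both empty-vector control series
    share the small nonspecific plateau ``bmax_null``.  ``bret50`` is the
    log-uniform range of the half-saturation ratio.  Additive Gaussian
    noise on net BRET has sd ``noise_sd_frac`` times the midpoint of the
    hit plateau range, a common scale for every series so that
    non-interactors and controls are identically distributed.
    """

    genes: list[str]
    true_interactors: list[str] = field(default_factory=list)
    bmax_hit: tuple[float, float] = (0.1, 0.3)
    bmax_null: float = 0.02
    bret50: tuple[float, float] = (0.5, 4.0)
    noise_sd_frac: float = 0.05
    n_replicates: int = 4
    x_grid: tuple[float, ...] = DEFAULT_X_GRID
    seed: int = 0
    geometry: int = 1536
    l460_nominal: float = 10000.0
    donor_background: float = 0.10
    x_jitter_frac: float = 0.02

    def validate(self) -> None:
        if not self.genes:
            raise ConfigError("BRET screen needs at least one gene")
        if not set(self.true_interactors) <= set(self.genes):
            raise ConfigError("true_interactors must be a subset of genes")
        if not (0 < self.bmax_hit[0] <= self.bmax_hit[1]):
            raise ConfigError("bmax_hit must be a positive (lo, hi) range")
        if not (0 < self.bret50[0] <= self.bret50[1]):
            raise ConfigError("bret50 must be a positive (lo, hi) range")
        if self.noise_sd_frac < 0 or self.x_jitter_frac < 0:
            raise ConfigError("noise fractions must be nonnegative")
        if self.n_replicates < 1 or len(self.x_grid) < 3:
            raise ConfigError("need >= 1 replicate and >= 3 titration points")
        if self.geometry not in GEOMETRIES:
            raise ConfigError(f"unknown geometry {self.geometry}")

    @property
    def noise_sd(self) -> float:
        return self.noise_sd_frac * (self.bmax_hit[0] + self.bmax_hit[1]) / 2.0


@dataclass
class BretScreenData:
    """White/black plate tables, plate map, and the generating truth."""

    white: pd.DataFrame
    black: pd.DataFrame
    plate_map: pd.DataFrame
    truth: pd.DataFrame


def generate_bret_screen(truth: BretScreenTruth) -> BretScreenData:
    """Simulate a full BRET saturation screen at the plate-table level.

    Every gene (and each empty-vector control series) gets
    ``n_replicates`` titration series over ``x_grid``: white-plate wells
    carry L460 and F535, the side-by-side black plate carries Venus FI at
    the same coordinates.  Donor-only baseline wells (white plate only)
    anchor the net-BRET subtraction.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    interactors = set(truth.true_interactors)
    sd = truth.noise_sd

    def draw_b50():
        lo, hi = truth.bret50
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    series = []  # (construct, role, bmax, b50)
    series.append((CTRL1_CONSTRUCT, "ctrl_acceptor_only", truth.bmax_null, draw_b50()))
    series.append((CTRL2_CONSTRUCT, "ctrl_donor_only", truth.bmax_null, draw_b50()))
    truth_rows = []
    for gene in truth.genes:
        bmax = (
            float(rng.uniform(*truth.bmax_hit)) if gene in interactors else truth.bmax_null
        )
        b50 = draw_b50()
        series.append((gene, "ppi", bmax, b50))
        truth_rows.append(
            {"gene": gene, "is_interactor": gene in interactors, "bmax": bmax, "bret50": b50}
        )

    white_rows, black_rows, map_rows = [], [], []
    idx = 0

    def add_well(construct, role, replicate, l460, f535, venus):
        nonlocal idx
        plate, well = _well_id(idx, truth.geometry)
        idx += 1
        white_id = f"plate{plate:02d}.white"
        white_rows.append({"plate_id": white_id, "well": well, "L460": l460, "F535": f535})
        map_rows.append(
            {
                "plate_id": white_id,
                "well": well,
                "role": role,
                "construct_or_compound": construct,
                "condition": "cancer_alone",
                "replicate": replicate,
            }
        )
        if venus is not None:
            black_id = f"plate{plate:02d}.black"
            black_rows.append({"plate_id": black_id, "well": well, "venus_fi": venus})
            map_rows.append(
                {
                    "plate_id": black_id,
                    "well": well,
                    "role": role,
                    "construct_or_compound": construct,
                    "condition": "cancer_alone",
                    "replicate": replicate,
                }
            )

    for construct, role, bmax, b50 in series:
        for rep in range(1, truth.n_replicates + 1):
            for x in truth.x_grid:
                x_true = x * (1.0 + rng.normal(0.0, truth.x_jitter_frac))
                x_true = max(x_true, 0.0)
                y_meas = float(saturation_model(x_true, bmax, b50) + rng.normal(0.0, sd))
                l460 = truth.l460_nominal
                f535 = l460 * (truth.donor_background + y_meas)
                add_well(construct, role, rep, l460, f535, x_true * l460)

    # donor-only baseline wells: flat background, no acceptor, white plate only
    for rep in range(1, truth.n_replicates + 1):
        for _ in truth.x_grid:
            ratio = truth.donor_background + rng.normal(0.0, sd)
            add_well(
                BASELINE_CONSTRUCT, "ctrl_donor_only", rep,
                truth.l460_nominal, truth.l460_nominal * ratio, None,
            )

    return BretScreenData(
        white=pd.DataFrame(white_rows),
        black=pd.DataFrame(black_rows),
        plate_map=pd.DataFrame(map_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# HTiP co-culture screen
# ---------------------------------------------------------------------------

@dataclass
class HtipScreenTruth:
    """Generating conditions for a synthetic immune co-culture screen.

    Inert compounds leave ~100% viability in both arms; each planted
    sensitizer reduces the +PBMC-arm cancer signal by its ``true_si``
    factor while leaving the -PBMC arm untouched.  Viability signals
    carry multiplicative lognormal noise with coefficient of variation
    ``assay_noise_cv``.
    """

    compounds: list[str]
    sensitizers: list[str] = field(default_factory=list)
    true_si: float = 5.0
    assay_noise_cv: float = 0.10
    plate_geometry: int = 384
    n_replicates: int = 3
    n_control_wells: int = 16
    cancer_signal: float = 10000.0
    blank_signal: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if not self.compounds:
            raise ConfigError("HTiP screen needs at least one compound")
        if not set(self.sensitizers) <= set(self.compounds):
            raise ConfigError("sensitizers must be a subset of compounds")
        if self.true_si <= 1:
            raise ConfigError("true_si must exceed 1 for a planted sensitizer")
        if self.assay_noise_cv < 0:
            raise ConfigError("assay_noise_cv must be nonnegative")
        if self.plate_geometry not in GEOMETRIES:
            raise ConfigError(f"unknown geometry {self.plate_geometry}")
        if self.n_replicates < 1 or self.n_control_wells < 2:
            raise ConfigError("need >= 1 replicate and >= 2 control wells per plate")


@dataclass
class HtipScreenData:
    measurements: pd.DataFrame
    plate_map: pd.DataFrame
    truth: pd.DataFrame


def generate_htip_screen(truth: HtipScreenTruth) -> HtipScreenData:
    """Simulate paired -PBMC/+PBMC viability plates with planted sensitizers.

    Each plate carries its own DMSO blank (PBMC/medium only) and positive
    (DMSO + cancer cells) control wells, placed first; compound wells
    fill the remainder, one well per compound per replicate per arm.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    sensitizers = set(truth.sensitizers)
    cv = truth.assay_noise_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))

    def noise_factor():
        if cv == 0:
            return 1.0
        return float(np.exp(rng.normal(-sigma**2 / 2.0, sigma)))  # unit mean

    n_rows, n_cols = GEOMETRIES[truth.plate_geometry]
    per_plate = n_rows * n_cols
    n_compound_wells = per_plate - 2 * truth.n_control_wells
    if n_compound_wells < 1:
        raise ConfigError("plate geometry too small for the requested control wells")

    meas_rows, map_rows = [], []
    for arm in ("minus_pbmc", "plus_pbmc"):
        jobs = [
            (compound, rep)
            for compound in truth.compounds
            for rep in range(1, truth.n_replicates + 1)
        ]
        n_plates = int(np.ceil(len(jobs) / n_compound_wells))
        job_iter = iter(jobs)
        for p in range(1, n_plates + 1):
            plate_id = f"{arm}.plate{p:02d}"
            idx = 0

            def add(role, construct, replicate, signal):
                nonlocal idx
                _, well = _well_id(idx, truth.plate_geometry)
                idx += 1
                meas_rows.append(
                    {"plate_id": plate_id, "well": well, "viability_signal": signal}
                )
                map_rows.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "role": role,
                        "construct_or_compound": construct,
                        "condition": arm,
                        "replicate": replicate,
                    }
                )

            for i in range(truth.n_control_wells):
                add("blank", "DMSO", i + 1, truth.blank_signal * noise_factor())
            for i in range(truth.n_control_wells):
                add(
                    "positive", "DMSO", i + 1,
                    truth.blank_signal + truth.cancer_signal * noise_factor(),
                )
            for _ in range(n_compound_wells):
                try:
                    compound, rep = next(job_iter)
                except StopIteration:
                    break
                base = truth.cancer_signal
                if arm == "plus_pbmc" and compound in sensitizers:
                    base = truth.cancer_signal / truth.true_si
                add("compound", compound, rep, truth.blank_signal + base * noise_factor())

    truth_df = pd.DataFrame(
        {
            "compound": truth.compounds,
            "is_sensitizer": [c in sensitizers for c in truth.compounds],
            "true_si": [truth.true_si if c in sensitizers else 1.0 for c in truth.compounds],
        }
    )
    return HtipScreenData(
        measurements=pd.DataFrame(meas_rows),
        plate_map=pd.DataFrame(map_rows),
        truth=truth_df,
    )


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseData:
    table: pd.DataFrame
    truth: dict


def generate_dose_response(
    top: float = 100.0,
    bottom: float = 0.0,
    hill: float = 1.0,
    ic50: float = 2e-7,
    n_doses: int = 8,
    dose_min: float = 1e-9,
    dose_max: float = 3e-5,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> DoseResponseData:
    """Sample a 4PL dose-response table with multiplicative Gaussian noise.

    Doses are log-spaced over [dose_min, dose_max] (molar).  The default
    midpoint, 0.2 uM, matches the potency scale of the STING-reporter
    induction curves this generator emulates.
    """
    if dose_max <= dose_min or dose_min <= 0:
        raise ConfigError("dose span must be positive with dose_min > 0")
    if n_doses < 2:
        raise ConfigError("need at least 2 doses")
    if ic50 <= 0:
        raise ConfigError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    doses = np.geomspace(dose_min, dose_max, n_doses)
    clean = four_pl(doses, top, bottom, hill, ic50)
    response = clean * (1.0 + rng.normal(0.0, noise_cv, size=n_doses))
    table = pd.DataFrame({"dose": doses, "response": response})
    truth = {"top": top, "bottom": bottom, "hill": hill, "ic50": ic50, "noise_cv": noise_cv}
    return DoseResponseData(table=table, truth=truth)
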