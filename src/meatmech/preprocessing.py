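"""From raw per-sample test records to per-product mean curves and scalar
mechanical signatures.

Each product is tested in three modes on several samples:

* tension: stretch ``lam`` from 1.0 up to the product's hyperelastic limit
  ``lambda_max`` (the largest stretch before any sample shows a notable
  stress drop),
* compression: stretch from 1.0 down to 0.9,
* simple shear: strain ``gam`` from 0.0 to 0.1.

Per-sample curves are resampled with an interpolating cubic spline onto 21
equidistant control points per mode, then averaged pointwise into a mean
curve with a standard-error band. Scalar signatures (origin-constrained
regression stiffnesses, tension-compression asymmetry at +/-10% stretch,
peak stress and stretch) are extracted from those curves. Loading and
unloading branches of a test enter as separate records for the same sample
and are averaged after resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "MODES",
    "N_GRID",
    "RawTestRecord",
    "MeanCurve",
    "ProductDataset",
    "Signature",
    "mode_grid",
    "resample_record",
    "aggregate_samples",
    "select_lambda_max",
    "stiffness",
    "signature",
    "process_product",
    "load_records",
    "write_records",
    "curves_frame",
    "signature_frame",
]

MODES = ("tension", "compression", "shear")
N_GRID = 21  # equidistant control points per mode

COMPRESSION_MIN = 0.9
SHEAR_MAX = 0.1


@dataclass
class RawTestRecord:
    """One test branch of one sample: a monotone control series (stretch or
    shear strain) with the measured nominal stress in kPa."""

    mode: str
    control: np.ndarray
    stress: np.ndarray
    sample_id: str = ""
    product_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.control = np.asarray(self.control, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.control.shape != self.stress.shape or self.control.ndim != 1:
            raise ValueError("control and stress must be 1-d arrays of equal length")
        if self.control.size < 4:
            raise ValueError("a test record needs at least 4 points")
        d = np.diff(self.control)
        if self.mode == "compression":
            if not np.all(d < 0):
                raise ValueError("compression control must strictly decrease from 1.0")
        elif not np.all(d > 0):
            raise ValueError(f"{self.mode} control must strictly increase")


@dataclass
class MeanCurve:
    """Processed signal of one mode: pointwise mean stress on the standard
    21-point grid, with SEM = SD/sqrt(n) and sample count n."""

    mode: str
    control_grid: np.ndarray
    mean_stress: np.ndarray
    sem_stress: np.ndarray
    n: int


@dataclass
class ProductDataset:
    product_id: str
    tension: MeanCurve
    compression: MeanCurve
    shear: MeanCurve
    lambda_max: float

    def curve(self, mode: str) -> MeanCurve:
        return {"tension": self.tension, "compression": self.compression, "shear": self.shear}[mode]


@dataclass
class Signature:
    """Scalar mechanical signature of a product (all stiffnesses in kPa)."""

    E_ten: float
    E_com: float
    E_shr: float
    E_mean: float
    E_sd: float
    asymmetry: float
    peak_stress: float
    peak_stretch: float


def mode_grid(mode: str, lambda_max: float | None = None, n_points: int = N_GRID) -> np.ndarray:
    """Standard control grid of a mode. The first point is always the
    reference state (lam = 1 or gam = 0), so compression runs 1.0 -> 0.9."""
    if mode == "tension":
        if lambda_max is None or lambda_max <= 1.0:
            raise ValueError("tension grid needs lambda_max > 1")
        return np.linspace(1.0, lambda_max, n_points)
    if mode == "compression":
        return np.linspace(1.0, COMPRESSION_MIN, n_points)
    if mode == "shear":
        return np.linspace(0.0, SHEAR_MAX, n_points)
    raise ValueError(f"unknown mode {mode!r}")


def resample_record(rec: RawTestRecord, grid: np.ndarray) -> np.ndarray:
    """Stress of ``rec`` on ``grid`` via an interpolating cubic spline
    (natural end conditions; no smoothing, so on-grid data pass through
    unchanged). Extrapolation beyond the record's range is refused."""
    order = np.argsort(rec.control)
    x, y = rec.control[order], rec.stress[order]
    lo, hi = float(np.min(grid)), float(np.max(grid))
    eps = 1e-12
    if x[0] > lo + eps or x[-1] < hi - eps:
        raise ValueError(
            f"record [{x[0]:g}, {x[-1]:g}] does not cover requested range [{lo:g}, {hi:g}]"
        )
    return CubicSpline(x, y, bc_type="natural")(grid)


def aggregate_samples(series: list[np.ndarray], grid: np.ndarray, mode: str) -> MeanCurve:
    """Pointwise mean and SEM = SD/sqrt(n) over resampled sample series."""
    if not series:
        raise ValueError("need at least one record")
    arr = np.vstack(series)
    if arr.shape[1] != grid.size:
        raise ValueError("series and grid lengths differ")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(grid.size)
    return MeanCurve(mode=mode, control_grid=np.asarray(grid, float), mean_stress=mean, sem_stress=sem, n=n)


def select_lambda_max(records: list[RawTestRecord], drop_fraction: float = 0.05) -> float:
    """Largest stretch up to which no tension sample's stress has dropped by
    more than ``drop_fraction`` of its running maximum (onset of failure).

    If no sample ever shows such a drop, the smallest common final stretch
    is returned with a warning.
    """
    if not records:
        raise ValueError("need at least one tension record")
    limits, dropped = [], False
    for rec in records:
        if rec.mode != "tension":
            raise ValueError("lambda_max selection uses tension records only")
        s = rec.stress
        runmax = np.maximum.accumulate(s)
        viol = np.nonzero(s < (1.0 - drop_fraction) * runmax)[0]
        if viol.size:
            limits.append(rec.control[viol[0] - 1] if viol[0] > 0 else rec.control[0])
            dropped = True
        else:
            limits.append(rec.control[-1])
    if not dropped:
        warnings.warn("no stress drop detected in any sample; using last common stretch")
    return float(min(limits))


def stiffness(curve: MeanCurve) -> float:
    """Origin-constrained regression stiffness of a mean curve (kPa).

    Tension/compression: strain eps = lam - 1, slope E = (eps.sigma)/(eps.eps).
    Shear: slope mu = (gam.tau)/(gam.gam), reported as E_shr = 3 mu (nu = 0.5).
    """
    x = curve.control_grid - (0.0 if curve.mode == "shear" else 1.0)
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("all-zero strain vector")
    slope = float(x @ curve.mean_stress) / denom
    return 3.0 * slope if curve.mode == "shear" else slope


def _interp(curve: MeanCurve, at: float) -> float:
    order = np.argsort(curve.control_grid)
    return float(CubicSpline(curve.control_grid[order], curve.mean_stress[order], bc_type="natural")(at))


def signature(ds: ProductDataset, tension_to_failure: list[RawTestRecord] | None = None) -> Signature:
    """Scalar signature of a product.

    The asymmetry is the tensile over compressive stress magnitude at
    +/-10% stretch, read off the mean curves (values above one mean the
    product is stiffer in tension). Peak stress/stretch are per-sample
    tensile maxima averaged over the failure records when supplied,
    otherwise the maximum of the mean tension curve.
    """
    E_ten = stiffness(ds.tension)
    E_com = stiffness(ds.compression)
    E_shr = stiffness(ds.shear)
    E = np.array([E_ten, E_com, E_shr])

    lam_t = min(1.1, ds.lambda_max)
    p_ten = _interp(ds.tension, lam_t)
    p_com = _interp(ds.compression, 0.9)
    if abs(p_com) < 1e-12:
        raise ValueError("compression stress vanishes at lam = 0.9; asymmetry undefined")
    asym = p_ten / abs(p_com)

    if tension_to_failure:
        peaks_s, peaks_l = [], []
        for rec in tension_to_failure:
            i = int(np.argmax(rec.stress))
            peaks_s.append(rec.stress[i])
            peaks_l.append(rec.control[i])
        peak_stress, peak_stretch = float(np.mean(peaks_s)), float(np.mean(peaks_l))
    else:
        i = int(np.argmax(ds.tension.mean_stress))
        peak_stress = float(ds.tension.mean_stress[i])
        peak_stretch = float(ds.tension.control_grid[i])

    return Signature(
        E_ten=E_ten,
        E_com=E_com,
        E_shr=E_shr,
        E_mean=float(E.mean()),
        E_sd=float(E.std(ddof=1)),
        asymmetry=float(asym),
        peak_stress=peak_stress,
        peak_stretch=peak_stretch,
    )


def process_product(
    records: list[RawTestRecord],
    product_id: str | None = None,
    lambda_max: float | None = None,
    drop_fraction: float = 0.05,
    n_points: int = N_GRID,
) -> ProductDataset:
    """Run the full per-product pipeline: select lambda_max from the tension
    records (unless given), resample every record onto its mode grid, and
    average into the three mean curves."""
    if not records:
        raise ValueError("no records supplied")
    if product_id is None:
        product_id = records[0].product_id
    by_mode: dict[str, list[RawTestRecord]] = {m: [] for m in MODES}
    for rec in records:
        by_mode[rec.mode].append(rec)
    for m in MODES:
        if not by_mode[m]:
            raise ValueError(f"product {product_id!r} has no {m} records")
    if lambda_max is None:
        lam_max = select_lambda_max(by_mode["tension"], drop_fraction)
    else:
        lam_max = float(lambda_max)
    curves = {}
    for m in MODES:
        grid = mode_grid(m, lam_max, n_points)
        curves[m] = aggregate_samples([resample_record(r, grid) for r in by_mode[m]], grid, m)
    return ProductDataset(
        product_id=product_id,
        tension=curves["tension"],
        compression=curves["compression"],
        shear=curves["shear"],
        lambda_max=lam_max,
    )


# ---------------------------------------------------------------------------
# CSV dialect: one file per record with columns control,stress_kPa; a sidecar
# manifest CSV (product_id,sample_id,mode,path) binds records to products.


def load_records(manifest_path: str | Path) -> list[RawTestRecord]:
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    required = {"product_id", "sample_id", "mode", "path"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} lacks columns {sorted(missing)}")
    if man.empty:
        raise ValueError(f"manifest {manifest_path} lists no records")
    records = []
    for row in man.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        df = pd.read_csv(p)
        records.append(
            RawTestRecord(
                mode=row.mode,
                control=df["control"].to_numpy(),
                stress=df["stress_kPa"].to_numpy(),
                sample_id=str(row.sample_id),
                product_id=str(row.product_id),
            )
        )
    return records


def write_records(records: list[RawTestRecord], out_dir: str | Path) -> Path:
    """Write records in the package CSV dialect; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.product_id}_{rec.sample_id}_{rec.mode}.csv"
        pd.DataFrame({"control": rec.control, "stress_kPa": rec.stress}).to_csv(
            out_dir / fname, index=False
        )
        rows.append({"product_id": rec.product_id, "sample_id": rec.sample_id, "mode": rec.mode, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def curves_frame(ds: ProductDataset) -> pd.DataFrame:
    """Mean curves of a product as a tidy frame (columns mode,control,mean,sem,n)."""
    parts = []
    for m in MODES:
        c = ds.curve(m)
        parts.append(
            pd.DataFrame(
                {"mode": m, "control": c.control_grid, "mean": c.mean_stress, "sem": c.sem_stress, "n": c.n}
            )
        )
    return pd.concat(parts, ignore_index=True)


def signature_frame(sigs: dict[str, Signature]) -> pd.DataFrame:
    return pd.DataFrame({pid: vars(s) for pid, s in sigs.items()}).T.rename_axis("product_id")
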