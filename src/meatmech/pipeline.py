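"""Pipeline orchestration: configuration, end-to-end runs, reports.

``run_pipeline`` binds the stages — load (or simulate) raw records,
preprocess into mean curves, extract signatures, sweep the one-/two-term
model library — and writes all artifacts (curve, signature, error-map and
decomposition CSVs, fitted-model JSON) into one output directory. Runs are
deterministic for a fixed seed, which is recorded in every artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discovery, preprocessing, synthetic
from .preprocessing import MODES, ProductDataset, Signature

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "plot_reports"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; round-trips through YAML."""

    manifest: str | None = None  # CSV manifest of raw records; None = simulate
    products: list[str] = field(default_factory=lambda: list(synthetic.PRODUCTS))
    out_dir: str = "results"
    seed: int = 0
    n_starts: int = 8
    n_samples: int = 5
    sample_scatter: float = 0.10
    noise_sd: float = 0.02
    drop_fraction: float = 0.05
    do_sweep: bool = True
    verbosity: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: RunConfig
    datasets: dict[str, ProductDataset]
    signatures: dict[str, Signature]
    error_maps: dict[str, discovery.ErrorMap]
    best_one: dict[str, discovery.FitResult]
    best_two: dict[str, discovery.FitResult]
    out_dir: Path


def _fit_to_json(fit: discovery.FitResult, seed: int) -> dict:
    return {
        "subset": list(fit.subset.active),
        "weights": fit.weights.w.tolist(),
        "exponents": fit.weights.wexp.tolist(),
        "mse": {"tension": fit.mse_ten, "compression": fit.mse_com, "shear": fit.mse_shr},
        "mean_mse": fit.mean_mse,
        "r2": fit.r2,
        "seed": seed,
    }


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute preprocess -> signatures -> sweep -> reports for every
    selected product and write all artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "run_config.yaml")

    per_product_records: dict[str, list] = {}
    if cfg.manifest is not None:
        records = preprocessing.load_records(cfg.manifest)
        for rec in records:
            per_product_records.setdefault(rec.product_id, []).append(rec)
        missing = [p for p in cfg.products if p not in per_product_records]
        if missing:
            raise ValueError(
                f"manifest {cfg.manifest} has no records for product(s) {missing}"
            )
    else:
        for i, pid in enumerate(cfg.products):
            gen = synthetic.GeneratorConfig(
                product_id=pid,
                n_samples=cfg.n_samples,
                sample_scatter=cfg.sample_scatter,
                noise_sd=cfg.noise_sd,
                seed=cfg.seed + i,
            )
            _, recs, _ = synthetic.generate_dataset(gen)
            per_product_records[pid] = recs

    datasets, signatures, error_maps, best_one, best_two = {}, {}, {}, {}, {}
    for pid in cfg.products:
        recs = per_product_records[pid]
        lam_max = synthetic.DEFAULT_LAMBDA_MAX.get(pid) if cfg.manifest is None else None
        ds = preprocessing.process_product(
            recs, product_id=pid, lambda_max=lam_max, drop_fraction=cfg.drop_fraction
        )
        datasets[pid] = ds
        signatures[pid] = preprocessing.signature(ds)
        preprocessing.curves_frame(ds).to_csv(out / f"curves_{pid}.csv", index=False)

        if cfg.do_sweep:
            emap, one, two = discovery.sweep_best_in_class(
                ds, discovery.OptConfig(n_starts=cfg.n_starts, seed=cfg.seed)
            )
            error_maps[pid], best_one[pid], best_two[pid] = emap, one, two
            pd.DataFrame(emap.matrix).to_csv(out / f"error_map_{pid}.csv", index=False)
            (out / f"model_{pid}.json").write_text(
                json.dumps(
                    {
                        "product_id": pid,
                        "best_one_term": _fit_to_json(one, cfg.seed),
                        "best_two_term": _fit_to_json(two, cfg.seed),
                    },
                    indent=2,
                )
            )
            dec = discovery.term_decomposition(two, ds)
            rows = []
            for m in MODES:
                grid = ds.curve(m).control_grid
                for t in range(8):
                    for g, v in zip(grid, dec[m][t]):
                        rows.append({"mode": m, "term": t + 1, "control": g, "stress": v})
            pd.DataFrame(rows).to_csv(out / f"decomposition_{pid}.csv", index=False)

    sig = preprocessing.signature_frame(signatures)
    sig["seed"] = cfg.seed
    sig.to_csv(out / "signatures.csv")
    return PipelineResult(cfg, datasets, signatures, error_maps, best_one, best_two, out)


def plot_reports(result: PipelineResult) -> list[Path]:
    """Write error-map heatmaps, per-mode fit curves with stacked term
    decomposition, and stiffness/asymmetry bar charts. Plot failures are
    logged, never fatal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = result.out_dir
    written: list[Path] = []
    try:
        pids = list(result.signatures)
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].bar(pids, [result.signatures[p].E_mean for p in pids])
        axes[0].set_ylabel("E_mean [kPa]")
        axes[1].bar(pids, [result.signatures[p].asymmetry for p in pids])
        axes[1].axhline(1.0, color="k", lw=0.8)
        axes[1].set_ylabel("tension/compression asymmetry at 10%")
        fig.tight_layout()
        p = out / "signatures.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    except Exception as exc:  # pragma: no cover - cosmetic path
        print(f"signature plot failed: {exc}")

    for pid, emap in result.error_maps.items():
        try:
            fig, ax = plt.subplots(figsize=(4.2, 3.6))
            with np.errstate(divide="ignore"):
                im = ax.imshow(np.log10(emap.matrix), cmap="RdBu_r")
            ax.set_xticks(range(8), [str(i) for i in range(1, 9)])
            ax.set_yticks(range(8), [str(i) for i in range(1, 9)])
            ax.set_title(f"{pid}: log10 mean MSE")
            fig.colorbar(im)
            fig.tight_layout()
            p = out / f"error_map_{pid}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
        except Exception as exc:  # pragma: no cover
            print(f"error-map plot for {pid} failed: {exc}")

    for pid, fit in result.best_two.items():
        try:
            ds = result.datasets[pid]
            dec = discovery.term_decomposition(fit, ds)
            fig, axes = plt.subplots(1, 3, figsize=(12, 3.4))
            for ax, m in zip(axes, MODES):
                grid = ds.curve(m).control_grid
                ax.stackplot(grid, *dec[m], labels=[f"w{t}" for t in range(1, 9)])
                ax.plot(grid, ds.curve(m).mean_stress, "k.", ms=4, label="data")
                ax.set_title(f"{pid} {m}")
                ax.set_xlabel("stretch" if m != "shear" else "shear strain")
                ax.set_ylabel("P [kPa]")
            axes[-1].legend(fontsize=6)
            fig.tight_layout()
            p = out / f"fit_{pid}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
        except Exception as exc:  # pragma: no cover
            print(f"fit plot for {pid} failed: {exc}")
    return written
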