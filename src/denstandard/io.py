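"""Table readers/writers, run configuration and the end-to-end pipeline.

All tabular exchange is UTF-8 comma-separated CSV with a mandatory header;
coordinates are planar km (no CRS handling anywhere in the package). Fit
reports and run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import record_from_row, records_to_frame
from .survey import CaptureHistory, TrapArray

log = logging.getLogger("denstandard")


# ---------------------------------------------------------------------------
# trap / capture tables

TRAP_COLUMNS = ["session", "trap_id", "x_km", "y_km"]
CAPTURE_COLUMNS = ["session", "individual_id", "occasion", "trap_id"]


def write_traps(traps: TrapArray, path):
    pd.DataFrame({
        "session": traps.session,
        "trap_id": traps.ids,
        "x_km": traps.xy[:, 0],
        "y_km": traps.xy[:, 1],
    }).to_csv(path, index=False)


def read_traps(path) -> list:
    """Read a trap-layout CSV; returns one TrapArray per session."""
    df = pd.read_csv(path)
    missing = set(TRAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trap table missing columns {sorted(missing)}")
    return [
        TrapArray(g["trap_id"].tolist(), g[["x_km", "y_km"]].to_numpy(float), session=str(s))
        for s, g in df.groupby("session", sort=True)
    ]


def write_captures(history: CaptureHistory, path):
    rows = []
    det = history.detections
    for i, ind in enumerate(history.individuals):
        for j, t in np.argwhere(det[i].T):  # (occasion, trap)
            rows.append((history.session, ind, int(j) + 1, history.traps.ids[t]))
    pd.DataFrame(rows, columns=CAPTURE_COLUMNS).to_csv(path, index=False)


def read_captures(path, traps: TrapArray, n_occasions: int | None = None) -> CaptureHistory:
    """Rebuild a capture history from the long-format detection CSV.

    Occasions are 1-based in the file. ``n_occasions`` must be given when
    the last occasions held no detections.
    """
    df = pd.read_csv(path)
    missing = set(CAPTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"capture table missing columns {sorted(missing)}")
    df = df[df["session"].astype(str) == traps.session]
    k = int(n_occasions or (df["occasion"].max() if len(df) else 1))
    inds = sorted(df["individual_id"].astype(str).unique())
    det = np.zeros((len(inds), traps.n_traps, k), dtype=np.uint8)
    for _, r in df.iterrows():
        det[inds.index(str(r["individual_id"])),
            traps.index_of(r["trap_id"]),
            int(r["occasion"]) - 1] = 1
    return CaptureHistory(tuple(inds), det, traps)


# ---------------------------------------------------------------------------
# studies table

MANDATORY_STUDY_COLUMNS = ["study_id", "landscape", "year", "method", "density", "se_density"]
_NUMERIC_STUDY_COLUMNS = [
    "year", "density", "se_density", "n_hat", "se_n", "mcp_area_km2",
    "mcp_perimeter_km", "original_buffer_km", "area_km2", "deforestation_rate",
    "trap_days", "n_cameras", "n_captures", "n_individuals",
]


class StudyTableError(ValueError):
    """Raised with a row-level report of malformed study records."""

    def __init__(self, problems):
        self.problems = problems
        super().__init__(
            "malformed study table rows:\n"
            + "\n".join(f"  row {i}: {msg}" for i, msg in problems)
        )


def read_studies_table(path) -> list:
    """Validated study-level density records from CSV.

    Unknown columns are preserved on each record; rows whose numeric fields
    fail to parse are collected into a single :class:`StudyTableError`
    listing the offending row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"studies table missing mandatory column(s) {missing}")
    problems, records = [], []
    for i, row in df.iterrows():
        d = row.to_dict()
        try:
            for c in _NUMERIC_STUDY_COLUMNS:
                if c in d and d[c] is not None and not pd.isna(d[c]):
                    d[c] = float(d[c])
            records.append(record_from_row(d))
        except (TypeError, ValueError) as err:
            problems.append((int(i) + 2, str(err)))  # +2: header + 1-based
    if problems:
        raise StudyTableError(problems)
    return records


def write_studies_table(records, path):
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass
class RunConfig:
    """Resolved configuration for an end-to-end pipeline run.

    The constants default to the package's reference analysis: a 1.96-sigma
    standardization buffer, a 2.45-sigma home-range radius, 2.9 tigers per
    breeding female, and the >25-bf / >1000-km² SSP rule.
    """

    seed: int = 0
    out_dir: str = "denstandard_run"
    # simulation stage
    grid_rows: int = 8
    grid_cols: int = 8
    spacing_km: float = 1.5
    true_density: float = 2.0
    g0: float = 0.05
    sigma_km: float = 2.5
    n_occasions: int = 90
    region_margin_sigmas: float = 4.0
    n_bias_replicates: int = 20
    # fitting
    mask_cell_km: float = 1.0
    mask_buffer_sigmas: float = 3.5
    # constants
    buffer_multiplier: float = 1.96
    home_range_multiplier: float = 2.45
    bf_ratio: float = 2.9
    ssp_min_bf: int = 25
    ssp_min_core_km2: float = 1000.0
    # meta stage
    meta_terms: tuple = ("forest_type", "disturbance")
    meta_n_landscapes: int = 60
    studies_csv: str | None = None  # standardize a real table instead of simulating
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "meta_terms" in data:
            data["meta_terms"] = tuple(data["meta_terms"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["meta_terms"] = list(d["meta_terms"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def pipeline_run(config: RunConfig) -> Path:
    """simulate -> fit -> standardize -> meta -> project, as configured.

    Writes each stage's outputs plus the resolved configuration and a
    manifest (file names, SHA-256 hashes) into ``config.out_dir``; returns
    that directory. Deterministic under a fixed seed.
    """
    from . import meta as _meta
    from . import project as _project
    from . import scr as _scr
    from . import simulate as _sim
    from . import standardize as _std
    from .datasets import forest_cover_2000_2012

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    ss = np.random.SeedSequence(config.seed)
    s_survey, s_bias, s_meta = ss.spawn(3)
    stage = "simulate"
    try:
        traps = _sim.place_traps(config.grid_rows, config.grid_cols, config.spacing_km)
        margin = config.region_margin_sigmas * config.sigma_km
        xmin, ymin, xmax, ymax = traps.extent()
        region = _sim.Rectangle(xmin - margin, ymin - margin, xmax + margin, ymax + margin)
        cfg = _sim.SurveyConfig(
            region=region, true_density=config.true_density, g0=config.g0,
            sigma_km=config.sigma_km, n_occasions=config.n_occasions,
            seed=config.seed,
        )
        centers, history = _sim.simulate_survey(cfg, traps, seed=s_survey)
        write_traps(traps, out / "traps.csv")
        write_captures(history, out / "captures.csv")

        stage = "fit"
        mask = _scr.make_mask(
            traps, config.mask_buffer_sigmas * config.sigma_km, config.mask_cell_km
        )
        fit = _scr.fit_scr([(history, mask)])
        buffer_km, buffer_se = fit.standard_buffer_km(config.buffer_multiplier)
        fit_report = {
            "density_per_100km2": fit.density,
            "se_density": fit.se_density,
            "g0": fit.g0, "se_g0": fit.se_g0,
            "sigma_km": fit.sigma_km, "se_sigma_km": fit.se_sigma_km,
            "log_lik": fit.log_lik,
            "standard_buffer_km": buffer_km,
            "se_standard_buffer_km": buffer_se,
            "home_range_km2": fit.home_range_area_km2(config.home_range_multiplier),
            "n_individuals": fit.n_individuals,
            "converged": fit.converged,
        }
        (out / "scr_fit.json").write_text(json.dumps(fit_report, indent=2))

        stage = "standardize"
        if config.studies_csv:
            studies = read_studies_table(config.studies_csv)
            corrected, n_corr = _std.correct_dataset(studies, buffer_km)
            write_studies_table(corrected, out / "studies_standardized.csv")
            log.info("standardized %d CR records with buffer %.2f km", n_corr, buffer_km)

        stage = "meta"
        meta_df = _sim.simulate_meta_dataset(
            _sim.MetaSimConfig(n_landscapes=config.meta_n_landscapes, seed=config.seed),
            seed=s_meta,
        )
        meta_df.to_csv(out / "meta_dataset.csv", index=False)
        mfit = _meta.fit_meta_lmm(meta_df, config.meta_terms, method="ML")
        meta_report = {
            "terms": list(config.meta_terms),
            "beta": mfit.beta.to_dict(),
            "se": mfit.se_beta.to_dict(),
            "tau2": mfit.tau2, "sigma2_eps": mfit.sigma2_eps,
            "log_lik": mfit.log_lik, "aicc": _meta.aicc(mfit),
            "marginal_r2": _meta.marginal_r2(mfit),
            "effects_percent": {k: _meta.effect_percent(v)
                                for k, v in mfit.beta.items() if k != "Intercept"},
        }
        (out / "meta_fit.json").write_text(json.dumps(meta_report, indent=2))

        stage = "project"
        table = forest_cover_2000_2012()
        b0 = float(np.exp(mfit.beta["Intercept"]))
        pm = float(np.exp(mfit.beta.get("forest_type[peat-montane]", 0.0)))
        dg = float(np.exp(mfit.beta.get("disturbance[logged]", 0.0)))
        dens = _project.densities_from_effects(b0, pm, dg)
        proj = _project.project_population(table, dens)
        proj.to_csv(out / "projection_2012.csv", index=False)

        stage = "bias"
        bias = _sim.run_bias_experiment(
            cfg, traps, config.n_bias_replicates,
            mask_cell_km=config.mask_cell_km,
            mask_buffer_sigmas=config.mask_buffer_sigmas,
            seed=s_bias,
        )
        bias.replicates.to_csv(out / "bias_replicates.csv", index=False)
        bias.summary.to_csv(out / "bias_summary.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "seed": config.seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
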