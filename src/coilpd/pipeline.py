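"""End-to-end orchestration: geometry -> flow -> metrics -> statistics.

``run_case`` carries one aneurysm through both post-coiling variants (VM
and RM) under identical pulsatile boundary conditions and reports the
peak-systole hemodynamic summaries.  ``run_cohort_study`` produces the
cohort-level report: a group-comparison table, ROC/Youden discrimination
of PD, VM-RM rank agreement, and the univariate -> multivariate logistic
selection.  Every random element flows from the single root seed, so any
output file is regenerable bit-identically from (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as cio
from .cohort import (
    CohortParams,
    CohortRecord,
    cohort_frame,
    cutoff_performance,
    fisher_exact,
    generate_cohort,
    logistic_fit,
    mann_whitney_u,
    roc_analysis,
    spearman_rho,
)
from .errors import DegenerateDataError, FitError, InputError
from .flow import (
    FluidProperties,
    InflowWaveform,
    SimulationConfig,
    make_waveform,
    solve_transient,
)
from .geometry import (
    AneurysmSpec,
    BranchSpec,
    CoilSurfaceSpec,
    apply_real_coiling,
    apply_virtual_coiling,
    build_pre_coiling,
)
from .metrics import HemodynamicSummary, summarize_at_peak

logger = logging.getLogger("coilpd.pipeline")

#: continuous Table-1-style variables reported by the cohort study
CONTINUOUS_VARS = [
    "max_size", "ver",
    "pmax_vm", "pave_vm", "vin_vm", "pd_vm",
    "pmax_rm", "pave_rm", "vin_rm", "pd_rm",
]
FLAG_VARS = ["pcom", "ruptured"]
LOGISTIC_COVARIATES = ["max_size", "ver", "pcom", "ruptured", "pd_vm", "pd_rm"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs."""

    geometry: AneurysmSpec = AneurysmSpec()
    coil: CoilSurfaceSpec = CoilSurfaceSpec()
    fluid: FluidProperties = FluidProperties()
    waveform: InflowWaveform = InflowWaveform()
    sim: SimulationConfig = SimulationConfig()
    cohort: CohortParams = CohortParams()
    grid_spacing: float = 0.25e-3  # m
    seed: int = 0
    outdir: Optional[str] = None
    verbosity: int = 1

    def effective_coil_seed(self) -> int:
        # all randomness flows from the root seed; the coil seed offsets it
        return (self.seed * 100_003 + self.coil.seed) % (2**31)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        d = {
            "geometry": enc(self.geometry),
            "coil": enc(self.coil),
            "fluid": enc(self.fluid),
            "waveform": enc(self.waveform),
            "sim": enc(self.sim),
            "grid_spacing": self.grid_spacing,
            "seed": self.seed,
            "outdir": self.outdir,
            "verbosity": self.verbosity,
        }
        d["cohort"] = enc(self.cohort)
        return d

    def science_hash(self) -> str:
        """Hash of the run-defining config (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k not in ("outdir", "verbosity")}
        return cio.config_hash(d)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        from .cohort import GroupParams, VariablePair

        def vp(x):
            return VariablePair(**x)

        def gp(x):
            x = dict(x)
            for k in ("pd", "pave", "vin"):
                x[k] = vp(x[k])
            for k in ("max_size", "ver"):
                x[k] = tuple(x[k])
            return GroupParams(**x)

        kw: dict = {}
        if "geometry" in d:
            g = dict(d["geometry"])
            if g.get("branch"):
                g["branch"] = BranchSpec(**g["branch"])
            kw["geometry"] = AneurysmSpec(**g)
        if "coil" in d:
            kw["coil"] = CoilSurfaceSpec(**d["coil"])
        if "fluid" in d:
            kw["fluid"] = FluidProperties(**d["fluid"])
        if "waveform" in d:
            w = dict(d["waveform"])
            if "harmonics" in w:
                w["harmonics"] = tuple(tuple(p) for p in w["harmonics"])
            kw["waveform"] = make_waveform(
                mean_velocity=w.get("mean_velocity", 0.65),
                period=w.get("period", 0.9),
                harmonics=w.get("harmonics", InflowWaveform().harmonics),
            )
        if "sim" in d:
            kw["sim"] = SimulationConfig(**d["sim"])
        if "cohort" in d:
            c = dict(d["cohort"])
            c["recanalized"] = gp(c["recanalized"])
            c["stable"] = gp(c["stable"])
            kw["cohort"] = CohortParams(**c)
        for k in ("grid_spacing", "seed", "outdir", "verbosity"):
            if k in d:
                kw[k] = d[k]
        return RunConfig(**kw)


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(cio.load_config_dict(path))


def _summary_row(s: HemodynamicSummary, cfg: RunConfig, chash: str) -> dict:
    return {
        "model": s.model,
        "pmax_pa": s.pmax,
        "pave_pa": s.pave,
        "vin_m_per_s": s.vin,
        "pd": s.pd,
        "peak_systole_s": s.peak_systole_time,
        "seed": cfg.seed,
        "config_hash": chash,
    }


def run_case(cfg: RunConfig) -> tuple[HemodynamicSummary, HemodynamicSummary]:
    """Build VM and RM from one spec, solve both transients, summarize both."""
    chash = cfg.science_hash()
    cio.log_kv("run_case.start", config_hash=chash, seed=cfg.seed)

    pre = build_pre_coiling(cfg.geometry, cfg.grid_spacing)
    vm = apply_virtual_coiling(pre, cfg.geometry)
    coil = replace(cfg.coil, mode="RM_rough", seed=cfg.effective_coil_seed())
    rm = apply_real_coiling(pre, cfg.geometry, coil)

    summaries = []
    for tag, geom in (("VM", vm), ("RM", rm)):
        series = solve_transient(geom, cfg.fluid, cfg.waveform, cfg.sim)
        s = summarize_at_peak(series, geom, cfg.fluid, cfg.sim, model=tag)
        cio.log_kv(
            "run_case.model", model=tag, pd=f"{s.pd:.6f}", pmax=f"{s.pmax:.3f}",
            pave=f"{s.pave:.3f}", vin=f"{s.vin:.6f}", t_peak=f"{s.peak_systole_time:.3f}",
            substeps=series.log.get("substeps"),
        )
        summaries.append((geom, series, s))

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [_summary_row(s, cfg, chash) for _, _, s in summaries]
        cio.write_summary_csv(out / "summaries.csv", rows)
        for (geom, series, s) in summaries:
            cio.write_vtk(out / f"{s.model.lower()}_peak.vtk", geom,
                          min(series.snapshots, key=lambda f: abs(f.time - s.peak_systole_time)))
            cio.write_stl(out / f"{s.model.lower()}_surface.stl", geom)
        cio.save_config_dict(cfg.to_dict(), out / "config.json")

    return summaries[0][2], summaries[1][2]


# ---------------------------------------------------------------------------
# cohort study
# ---------------------------------------------------------------------------

def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} +/- {np.std(x, ddof=1):.2f}"


def table1(frame: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison table mirroring the published cohort table layout."""
    rec = frame[frame["group"] == "recanalized"]
    sta = frame[frame["group"] == "stable"]
    rows = []
    for var in CONTINUOUS_VARS:
        try:
            p = mann_whitney_u(rec[var], sta[var])["p"]
        except DegenerateDataError:
            logger.warning("table1: degenerate data for %s; p recorded as NaN", var)
            p = np.nan
        rows.append({
            "variable": var, "test": "mann_whitney",
            "recanalized": _mean_sd(rec[var].to_numpy()),
            "stable": _mean_sd(sta[var].to_numpy()),
            "p": p,
        })
    for var in FLAG_VARS:
        a, b = int(rec[var].sum()), int((~rec[var].astype(bool)).sum())
        c, d = int(sta[var].sum()), int((~sta[var].astype(bool)).sum())
        rows.append({
            "variable": var, "test": "fisher_exact",
            "recanalized": f"{a} ({100.0 * a / len(rec):.1f}%)",
            "stable": f"{c} ({100.0 * c / len(sta):.1f}%)",
            "p": fisher_exact([[a, b], [c, d]]),
        })
    return pd.DataFrame(rows)


def run_cohort_study(cfg: RunConfig, records: Optional[list[CohortRecord]] = None) -> dict:
    """Cohort generation plus the full statistical battery.

    Pass ``records`` (e.g. assembled from simulated cases) to skip the
    synthetic generator.
    """
    chash = cfg.science_hash()
    if records is None:
        records = generate_cohort(cfg.cohort, seed=cfg.seed)
    frame = cohort_frame(records)
    if frame["group"].nunique() < 2:
        raise InputError("cohort must contain both outcome groups")
    labels = (frame["group"] == "recanalized").to_numpy()

    tab1 = table1(frame)

    roc_rows = []
    for score_col in ("pd_rm", "pd_vm"):
        roc = roc_analysis(frame[score_col].to_numpy(), labels)
        perf = cutoff_performance(frame[score_col].to_numpy(), labels, roc.youden_cutoff)
        roc_rows.append({
            "score": score_col, "auc": roc.auc, "cutoff": roc.youden_cutoff,
            "sensitivity": perf["sensitivity"], "specificity": perf["specificity"],
        })
    roc_tab = pd.DataFrame(roc_rows)

    corr_rows = []
    for base in ("pd", "pmax", "pave", "vin"):
        sp = spearman_rho(frame[f"{base}_vm"], frame[f"{base}_rm"])
        corr_rows.append({"parameter": base, "rho": sp["rho"], "p": sp["p"]})
    corr_tab = pd.DataFrame(corr_rows)

    covs = frame[LOGISTIC_COVARIATES].astype(float)
    logistic: dict = {}
    try:
        logistic["univariate"] = logistic_fit(covs, labels, mode="univariate")
        logistic["multivariate"] = logistic_fit(covs, labels, mode="multivariate")
    except (FitError, DegenerateDataError) as exc:  # logged, study still reported
        logger.warning("cohort logistic regression skipped: %s", exc)
        logistic["error"] = str(exc)

    report = {
        "cohort": frame,
        "table1": tab1,
        "roc": roc_tab,
        "correlation": corr_tab,
        "logistic": logistic,
        "config_hash": chash,
        "seed": cfg.seed,
    }

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "cohort.csv", float_format="%.12g")
        tab1.to_csv(out / "table1.csv", index=False, float_format="%.12g")
        roc_tab.to_csv(out / "roc.csv", index=False, float_format="%.12g")
        corr_tab.to_csv(out / "correlation.csv", index=False, float_format="%.12g")
        with open(out / "report.txt", "w") as fh:
            fh.write(f"coilpd cohort study  seed={cfg.seed}  config={chash}\n\n")
            fh.write("Group comparison (mean +/- SD; Mann-Whitney / Fisher p):\n")
            fh.write(tab1.to_string(index=False))
            fh.write("\n\nROC discrimination of recurrence:\n")
            fh.write(roc_tab.to_string(index=False))
            fh.write("\n\nVM-RM Spearman agreement:\n")
            fh.write(corr_tab.to_string(index=False))
            if "multivariate" in logistic:
                fh.write("\n\nMultivariate logistic model (selected covariates):\n")
                meta = logistic["multivariate"]["_meta"]
                for name in meta["included"]:
                    r = logistic["multivariate"][name]
                    fh.write(
                        f"  {name}: OR={r['OR']:.3g} CI95=({r['CI95'][0]:.3g}, "
                        f"{r['CI95'][1]:.3g}) p={r['p']:.4f}\n"
                    )
            fh.write("\n")
        cio.save_config_dict(cfg.to_dict(), out / "config.json")
        cio.log_kv("run_cohort_study.done", outdir=str(out), config_hash=chash)

    return report


def records_from_cases(
    case_results: list[tuple[str, str, HemodynamicSummary, HemodynamicSummary, AneurysmSpec]],
    ver_percent: float = 25.0,
) -> list[CohortRecord]:
    """Assemble cohort records from simulated (VM, RM) case summaries.

    Morphological covariates derive from each spec (max size = dome
    diameter in mm); VER is a nominal packing percentage since coil
    micro-structure is not modeled.
    """
    out = []
    for case_id, group, s_vm, s_rm, spec in case_results:
        out.append(CohortRecord(
            case_id=case_id, group=group,
            pd_vm=s_vm.pd, pd_rm=s_rm.pd,
            pmax_vm=s_vm.pmax, pmax_rm=s_rm.pmax,
            pave_vm=s_vm.pave, pave_rm=s_rm.pave,
            vin_vm=s_vm.vin, vin_rm=s_rm.vin,
            max_size=2.0e3 * spec.dome_radius, ver=ver_percent,
            pcom=spec.branch is not None, ruptured=False,
        ))
    return out
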