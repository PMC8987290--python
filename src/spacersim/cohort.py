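"""Simulation-phase cohort runs: cases x spacer scenarios -> metric table.

For every case a phantom is generated, the four spacer scenarios are
simulated (S0 skips the mechanical solve), an SBRT plan is synthesized
and scaled on each resulting anatomy, and one row of separation and dose
metrics is emitted.  The table feeds the decision-support training stage
directly.  Runs are resumable: rows already present in the output CSV are
not recomputed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import dosimetry, dss, geometry, phantom, simulate
from .grid import StructureSet, VoxelGrid

__all__ = [
    "CohortSettings",
    "run_cohort",
    "features_frame",
    "bayes_frame",
    "train_dss",
]

log = logging.getLogger("spacersim.cohort")

#: schema version written as a header comment in cohort CSVs
COHORT_SCHEMA = "spacersim-cohort-v1"

SECTION_GROUP_MASKS = {"D1D2": ("D1", "D2"), "D3": ("D3",), "D4": ("D4",)}


@dataclass
class CohortSettings:
    """Study conditions for a simulation-phase cohort.

    Twenty cases with four scenarios each mirror the simulation-phase
    design; the per-case spacer travel is drawn uniformly from
    ``push_range_mm`` to emulate variable injected volume and spread.
    """

    n_cases: int = 20
    base_seed: int = 100
    grid_n: int = 72
    spacing_mm: float = 2.0
    scenarios: Tuple[str, ...] = ("S0", "S1", "S2", "S3")
    per_section_volume_ml: float = 9.0
    push_range_mm: Tuple[float, float] = (4.0, 10.0)
    falloff_mm: float = 5.0
    noise_amp: float = 0.0
    desired_bed_gy: float = 70.0
    sim: simulate.SimulationSettings = field(default_factory=simulate.SimulationSettings)

    def grid(self) -> VoxelGrid:
        return phantom.default_grid(self.grid_n, self.spacing_mm)

    def case_seed(self, i: int) -> int:
        return int(self.base_seed + i)


def _case_metrics(
    s: StructureSet,
    dose,
    settings: CohortSettings,
) -> Dict[str, float]:
    """Separation + dose metrics for one (possibly warped) structure set."""
    grid = s.grid
    row: Dict[str, float] = {}
    sd = geometry.target_signed_distance(s["HOP"], grid)
    for oar in ("duodenum", "stomach", "bowel"):
        curve = geometry.ovh(s["HOP"], s[oar], grid, sd=sd)
        row[f"l1cc_{oar}_mm"] = curve.threshold(1)
        if oar == "duodenum":
            l20 = curve.threshold(20)
            row["l20cc_duodenum_mm"] = np.nan if l20 is None else l20
    for group, names in SECTION_GROUP_MASKS.items():
        mask = np.zeros(grid.shape, bool)
        for n in names:
            mask |= s[n]
        row[f"l1cc_{group}_mm"] = geometry.ovh(s["HOP"], mask, grid, sd=sd).threshold(1)
    for oar in ("duodenum", "stomach", "bowel"):
        row[f"v33_{oar}_cc"] = dosimetry.dvh_volume_at_dose(dose, s[oar], 33.0)
        row[f"v20_{oar}_cc"] = dosimetry.dvh_volume_at_dose(dose, s[oar], 20.0)
    row["ptv_v33_pct"] = dosimetry.dvh_volume_at_dose(dose, s["PTV"], 33.0, percent=True)
    row["coverage_scale"] = dose.meta.get("coverage_scale", np.nan)
    for variant, tag in (("duodenum_only", "duo"), ("all_proximal", "all")):
        r = dosimetry.max_bed(dose, s, variant)
        row[f"maxbed_{tag}_gy"] = r.bed_gy
        row[f"maxbed_{tag}_capped"] = float(r.capped)
    return row


def _simulation_quality(
    s: StructureSet,
    post: StructureSet,
    scenario: phantom.SpacerScenario,
    pre_profile: geometry.RNNDProfile,
    pre_wall: int,
    sec_bins: Dict[str, np.ndarray],
) -> Dict[str, float]:
    """Deformation sanity metrics comparing pre and post anatomy.

    The post profile is computed about the pre-injection origin and zero
    direction so bins are comparable.  Injected bins cover the scenario's
    duodenal sections; far bins lie more than 90 degrees from all of them.
    """
    ma = geometry.extract_margin(post["duodenum"], post.grid)
    mb = geometry.extract_margin(post["HOP"], post.grid)
    post_profile = geometry.rnnd(
        ma,
        mb,
        origin=pre_profile.origin_mm,
        bin_width_deg=pre_profile.bin_width_deg,
        reference_deg=pre_profile.reference_deg,
    )
    injected_sections = [
        name for g in scenario.sections for name in SECTION_GROUP_MASKS[g]
    ]
    inj = np.unique(np.concatenate([sec_bins[n] for n in injected_sections]))
    n_bins = pre_profile.n_bins
    centers = pre_profile.bin_centers_deg
    inj_centers = centers[inj]
    ang_dist = np.min(
        np.abs((centers[:, None] - inj_centers[None, :] + 180.0) % 360.0 - 180.0),
        axis=1,
    )
    far = np.flatnonzero(ang_dist > 90.0)

    def bin_delta(bins: np.ndarray) -> float:
        if bins.size == 0:
            return 0.0
        a = post_profile.mean_mm[bins]
        b = pre_profile.mean_mm[bins]
        ok = np.isfinite(a) & np.isfinite(b)
        return float(np.mean(a[ok] - b[ok])) if ok.any() else 0.0

    post_wall = int(post.duodenum_wall().sum())
    return {
        "rnnd_injected_delta_mm": bin_delta(inj),
        "rnnd_far_delta_mm": bin_delta(far),
        "wall_volume_change_frac": abs(post_wall - pre_wall) / max(pre_wall, 1),
        "dsc_duodenum_pre_post": geometry.dsc(s["duodenum"], post["duodenum"]),
    }


def run_cohort(
    settings: Optional[CohortSettings] = None,
    out_csv: Optional[Path] = None,
) -> pd.DataFrame:
    """Run (or resume) the cohort; returns the full metric table.

    Per-case failures are logged and skipped; the failure list is attached
    as ``df.attrs['failures']`` so callers can exit nonzero.
    """
    settings = settings or CohortSettings()
    out_csv = Path(out_csv) if out_csv is not None else None

    done: Dict[Tuple[int, str], Dict] = {}
    if out_csv is not None and out_csv.exists():
        old = pd.read_csv(out_csv, comment="#")
        for _, r in old.iterrows():
            done[(int(r["case"]), str(r["scenario"]))] = r.to_dict()
        log.info("resuming: %d rows already present", len(done))

    rows: List[Dict] = []
    failures: List[Tuple[int, str, str]] = []
    for i in range(settings.n_cases):
        seed = settings.case_seed(i)
        pending = [sc for sc in settings.scenarios if (i, sc) not in done]
        rows.extend(done[(i, sc)] for sc in settings.scenarios if (i, sc) in done)
        if not pending:
            continue
        t0 = time.time()
        try:
            s = phantom.generate_phantom(seed, grid=settings.grid())
        except Exception as exc:  # pragma: no cover - defensive
            log.error("case %d: phantom generation failed: %s", i, exc)
            failures.extend((i, sc, str(exc)) for sc in pending)
            continue
        push = float(
            np.random.default_rng(10_000_000 + seed).uniform(*settings.push_range_mm)
        )
        base_row = {
            "case": i,
            "seed": seed,
            "gap_mm": s.meta["anatomy"]["gap_mm"],
            "push_mm": push,
        }
        pre_profile = geometry.duodenal_rnnd(s)
        pre_wall = int(s.duodenum_wall().sum())
        sec_bins = {
            name: geometry.section_bins(s, pre_profile, name)
            for name in ("D1", "D2", "D3", "D4")
        }
        s0_metrics: Optional[Dict[str, float]] = None
        for sc in settings.scenarios:
            if (i, sc) in done:
                if sc == "S0":
                    s0_metrics = {
                        k: done[(i, sc)][k]
                        for k in done[(i, sc)]
                        if k.startswith(("l1cc_", "maxbed_"))
                    }
                continue
            try:
                sim_quality: Dict[str, float] = {
                    "rnnd_injected_delta_mm": 0.0,
                    "rnnd_far_delta_mm": 0.0,
                    "wall_volume_change_frac": 0.0,
                    "dsc_duodenum_pre_post": 1.0,
                }
                if sc == "S0":
                    post = s
                else:
                    scenario = phantom.SpacerScenario(
                        sc, per_section_volume_ml=settings.per_section_volume_ml
                    )
                    sim_settings = replace(settings.sim, push_mm=push)
                    post = simulate.simulate_scenario(s, scenario, sim_settings).post
                    sim_quality = _simulation_quality(
                        s, post, scenario, pre_profile, pre_wall, sec_bins
                    )
                dose = phantom.synthesize_dose(
                    post,
                    falloff_mm=settings.falloff_mm,
                    noise_amp=settings.noise_amp,
                    seed=seed,
                )
                metrics = _case_metrics(post, dose, settings)
                row = {**base_row, "scenario": sc, **metrics, **sim_quality}
                if sc == "S0":
                    s0_metrics = metrics
                if s0_metrics is not None:
                    row["dl1cc_duo_mm"] = max(
                        0.0, metrics["l1cc_duodenum_mm"] - s0_metrics["l1cc_duodenum_mm"]
                    )
                    row["dmaxbed_p1_gy"] = (
                        metrics["maxbed_duo_gy"] - s0_metrics["maxbed_all_gy"]
                    )
                    row["dmaxbed_p2_gy"] = (
                        metrics["maxbed_all_gy"] - s0_metrics["maxbed_all_gy"]
                    )
                rows.append(row)
                log.info("case %d %s done in %.1fs", i, sc, time.time() - t0)
                t0 = time.time()
            except Exception as exc:
                log.error("case %d %s failed: %s", i, sc, exc)
                failures.append((i, sc, str(exc)))

    df = pd.DataFrame(rows).sort_values(["case", "scenario"]).reset_index(drop=True)
    df.attrs["failures"] = failures
    if out_csv is not None:
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        with open(out_csv, "w") as fh:
            fh.write(f"# {COHORT_SCHEMA}\n")
            df.to_csv(fh, index=False)
    return df


# ---------------------------------------------------------------------------
# DSS training tables
# ---------------------------------------------------------------------------

def features_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Pre-injection features: one row per case (from the S0 rows)."""
    s0 = df[df["scenario"] == "S0"].copy()
    out = s0[
        ["case", "l1cc_duodenum_mm", "l1cc_stomach_mm", "l1cc_bowel_mm"]
    ].copy()
    out["min_l1cc_mm"] = out[
        ["l1cc_duodenum_mm", "l1cc_stomach_mm", "l1cc_bowel_mm"]
    ].min(axis=1)
    out["pre_maxbed_gy"] = s0["maxbed_all_gy"].values
    return out.reset_index(drop=True)


def bayes_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Long-format training rows for the Bayesian benefit regression.

    Every simulated spacer row contributes two observations: the P1
    target (duodenum-only constraints, X = 0) and the P2 target (all
    proximal constraints, X = 1).
    """
    sim_rows = df[df["scenario"] != "S0"]
    recs = []
    for _, r in sim_rows.iterrows():
        for x, col in ((0.0, "dmaxbed_p1_gy"), (1.0, "dmaxbed_p2_gy")):
            recs.append(
                {
                    "case": r["case"],
                    "scenario": r["scenario"],
                    "x_indicator": x,
                    "dl1cc_duo_mm": r["dl1cc_duo_mm"],
                    "dmaxbed_gy": r[col],
                }
            )
    return pd.DataFrame(recs)


def train_dss(
    df: pd.DataFrame, seed: int = 0, n_draws: int = 10000
) -> Tuple[dss.NNMaxBEDModel, dss.ThresholdModel, dss.BayesianSpacerModel]:
    """Train all three decision-support components from a cohort table."""
    feats = features_frame(df)
    nn = dss.train_maxbed_nn(
        feats[["l1cc_duodenum_mm", "l1cc_stomach_mm", "l1cc_bowel_mm"]].values,
        feats["pre_maxbed_gy"].values,
        seed=seed,
    )
    threshold = dss.fit_threshold_model(
        feats["min_l1cc_mm"].values, feats["pre_maxbed_gy"].values
    )
    bf = bayes_frame(df).dropna()
    bayes = dss.fit_bayes_lm(
        bf["x_indicator"].values,
        bf["dl1cc_duo_mm"].values,
        bf["dmaxbed_gy"].values,
        n_draws=n_draws,
        seed=seed,
    )
    return nn, threshold, bayes
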