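"""End-to-end study model: generate/ingest paired trials, extract per-stride
measures, and fit the three-way agreement analysis.

The central objects follow the model/results convention of statistical
modelling packages: :class:`GaitStabilityStudy` holds the paired stride
table (and per-trial Lyapunov exponents) plus the analysis configuration;
``fit()`` returns a :class:`StudyResults` carrying the group summary table
with repeated-measures ANOVA and control-referenced post-hoc tests, the
Bland-Altman agreement grid, and the ICC(A,1) reliability grid, with
``summary()`` rendering the report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .agreement import (AgreementResult, AnovaResult, ICCResult, bland_altman,
                        icc_a1, rm_anova_with_posthoc)
from .errors import (GaitStabError, InsufficientStridesError,
                     UndefinedICCError)
from .events import (GaitEvents, detect_gait_events, exclude_turn_strides,
                     match_strides)
from .lyapunov import EmbeddingSpec, lyapunov_exponent
from .mos import compute_mos, extrapolated_com
from .spatiotemporal import compute_stride_measures, rms_variability
from .synthetic import StudySpec, generate_study
from .trajectory import StabilityParams, Trajectory

logger = logging.getLogger("gaitstab")

#: measures compared stride-by-stride between systems
PAIRED_MEASURES = ("ml_mos", "ap_mos", "step_width", "step_length")
#: stride-table column behind each report measure name
_MEASURE_COLUMN = {
    "speed": "speed",
    "ml_mos": "min_ml_mos",
    "ap_mos": "ap_mos",
    "step_width": "step_width",
    "step_length": "step_length",
}
#: ANOVA is run on these report measures (matching the published table)
ANOVA_MEASURES = ("speed", "ml_mos", "ap_mos", "ml_lyapunov", "ap_lyapunov",
                  "step_width_rms", "step_length_rms", "step_width",
                  "step_length")
SYSTEMS = ("reference", "degraded")


@dataclass
class AnalysisConfig:
    """All pipeline thresholds in one place (defaults per the study design)."""

    cutoff: float = 6.0  # Hz, zero-phase Butterworth on positions
    filter_order: int = 4
    turn_angle: float = 30.0  # deg, turn-stride exclusion threshold
    match_tolerance: float = 0.15  # s, between-system heel-strike matching
    alpha: float = 0.05
    loa_multiplier: float = 1.96
    control_condition: str = "normal"
    landmark: str = "ball"
    compute_lyapunov: bool = True
    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_trial_pair(
    ref: Trajectory,
    deg: Trajectory,
    params: StabilityParams,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Filter, detect, measure and pair the strides of one two-system trial.

    Returns one row per matched stride with ``<measure>_reference`` /
    ``<measure>_degraded`` columns; strides flagged as turns or unmatched
    between systems are dropped.
    """
    config = config or AnalysisConfig()

    def _measures(traj: Trajectory) -> pd.DataFrame:
        f = traj.filtered(config.cutoff, config.filter_order)
        ev = exclude_turn_strides(f, detect_gait_events(f), config.turn_angle)
        meas = compute_stride_measures(f, ev, params,
                                       landmark=config.landmark)
        xcom = extrapolated_com(f, params)
        mos = compute_mos(f, xcom, ev, params, landmark=config.landmark)
        merged = meas.merge(mos, on=["foot", "stride"], how="left")
        return merged, ev

    meas_r, ev_r = _measures(ref)
    meas_d, ev_d = _measures(deg)
    pairing = match_strides(ev_r, ev_d, config.match_tolerance)

    meas_r = meas_r.set_index(["foot", "stride"])
    meas_d = meas_d.set_index(["foot", "stride"])
    rows = []
    cols = ["speed", "step_length", "step_width", "ap_mos", "min_ml_mos",
            "stride_time"]
    for side, side_pairs in pairing.pairs.items():
        for i, j in side_pairs:
            if (side, i) not in meas_r.index or (side, j) not in meas_d.index:
                continue
            rr = meas_r.loc[(side, i)]
            rd = meas_d.loc[(side, j)]
            row = {"foot": side, "stride_reference": i, "stride_degraded": j,
                   "hs_time": float(rr["hs_time"])}
            for c in cols:
                row[f"{c}_reference"] = float(rr[c])
                row[f"{c}_degraded"] = float(rd[c])
            rows.append(row)
    df = pd.DataFrame(rows)
    logger.info(
        "trial %s/%s/%s: %d paired strides (%d/%d detected, "
        "%d/%d turn-excluded)",
        ref.subject, ref.condition, ref.trial, len(df),
        sum(ev_r.n_strides(s) for s in ("left", "right")),
        sum(ev_d.n_strides(s) for s in ("left", "right")),
        sum(len(ev_r.excluded[s]) for s in ("left", "right")),
        sum(len(ev_d.excluded[s]) for s in ("left", "right")))
    return df


def trial_lyapunov(
    traj: Trajectory,
    params: StabilityParams,
    config: AnalysisConfig,
) -> dict[str, float]:
    """Short-term Lyapunov exponents of dimensionless CoM velocity (AP, ML).

    The trajectory is filtered, events detected, and the first
    ``embedding.n_strides`` right-foot gait cycles used.  Raises
    ``InsufficientStridesError`` when the trial is too short.
    """
    f = traj.filtered(config.cutoff, config.filter_order)
    ev = detect_gait_events(f)
    disp = f.com[-1, :2] - f.com[0, :2]
    n = np.linalg.norm(disp)
    ap = disp / n if n > 1e-9 else np.array([1.0, 0.0])
    ml = np.array([-ap[1], ap[0]])
    vel = f.com_vel[:, :2] / params.speed_scale
    starts = ev.feet["right"].heel_strikes
    out = {}
    for axis, vec in (("ap", ap), ("ml", ml)):
        curve = lyapunov_exponent(vel @ vec, starts, config.embedding)
        out[axis] = float(curve.exponent)
    return out


class GaitStabilityStudy:
    """Model object: paired stride data + configuration; ``fit()`` -> results."""

    def __init__(
        self,
        stride_pairs: pd.DataFrame,
        lyapunov: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
        meta: dict | None = None,
    ) -> None:
        self.stride_pairs = stride_pairs.reset_index(drop=True)
        self.lyapunov = lyapunov
        self.config = config or AnalysisConfig()
        self.meta = dict(meta or {})
        self.notices: list[str] = []

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_synthetic(
        cls,
        spec: StudySpec | None = None,
        config: AnalysisConfig | None = None,
    ) -> "GaitStabilityStudy":
        """Generate a synthetic paired study and run the full pipeline on it."""
        spec = spec or StudySpec()
        config = config or AnalysisConfig()
        data = generate_study(spec)
        frames = []
        lyap_rows = []
        notices = []
        for rec in data.trials:
            params = StabilityParams(rec.leg_length, spec.gravity)
            try:
                df = analyze_trial_pair(rec.reference, rec.degraded, params,
                                        config)
            except GaitStabError as exc:
                notices.append(
                    f"trial {rec.subject}/{rec.condition}/{rec.trial}: "
                    f"pipeline failed ({exc})")
                continue
            df.insert(0, "subject", rec.subject)
            df.insert(1, "condition", rec.condition)
            df.insert(2, "trial", rec.trial)
            frames.append(df)
            if config.compute_lyapunov:
                for system, traj in (("reference", rec.reference),
                                     ("degraded", rec.degraded)):
                    try:
                        lam = trial_lyapunov(traj, params, config)
                    except InsufficientStridesError as exc:
                        notices.append(
                            f"trial {rec.subject}/{rec.condition}/"
                            f"{rec.trial} [{system}]: Lyapunov skipped "
                            f"({exc})")
                        continue
                    for axis, val in lam.items():
                        lyap_rows.append({
                            "subject": rec.subject,
                            "condition": rec.condition,
                            "trial": rec.trial,
                            "system": system,
                            "axis": axis,
                            "exponent": val,
                        })
        stride_pairs = pd.concat(frames, ignore_index=True)
        lyap = pd.DataFrame(lyap_rows) if lyap_rows else None
        model = cls(stride_pairs, lyapunov=lyap, config=config,
                    meta={"seed": spec.seed, "n_subjects": spec.n_subjects,
                          "conditions": list(spec.conditions),
                          "source": "synthetic"})
        model.notices.extend(notices)
        model.ground_truth = data.ground_truth()
        model.study_data = data
        return model

    @classmethod
    def from_trial_pairs(
        cls,
        trial_pairs,
        config: AnalysisConfig | None = None,
        meta: dict | None = None,
    ) -> "GaitStabilityStudy":
        """Build from (reference, degraded, leg_length) trajectory triples."""
        config = config or AnalysisConfig()
        frames = []
        lyap_rows = []
        model_notices = []
        for ref, deg, leg_length in trial_pairs:
            params = StabilityParams(leg_length)
            df = analyze_trial_pair(ref, deg, params, config)
            df.insert(0, "subject", ref.subject or "S01")
            df.insert(1, "condition", ref.condition or "normal")
            df.insert(2, "trial", ref.trial if ref.trial is not None else 0)
            frames.append(df)
            if config.compute_lyapunov:
                for system, traj in (("reference", ref), ("degraded", deg)):
                    try:
                        lam = trial_lyapunov(traj, params, config)
                    except InsufficientStridesError as exc:
                        model_notices.append(
                            f"trial {ref.subject}/{ref.condition}: Lyapunov "
                            f"skipped ({exc})")
                        continue
                    for axis, val in lam.items():
                        lyap_rows.append({
                            "subject": ref.subject or "S01",
                            "condition": ref.condition or "normal",
                            "trial": ref.trial or 0,
                            "system": system, "axis": axis, "exponent": val})
        model = cls(pd.concat(frames, ignore_index=True),
                    lyapunov=pd.DataFrame(lyap_rows) if lyap_rows else None,
                    config=config, meta=meta)
        model.notices.extend(model_notices)
        return model

    @classmethod
    def from_saved(cls, directory,
                   config: AnalysisConfig | None = None) -> "GaitStabilityStudy":
        """Rebuild the model from CSVs written by ``StudyResults.to_csv``."""
        directory = Path(directory)
        stride_pairs = pd.read_csv(directory / "stride_table.csv")
        lyap_path = directory / "lyapunov.csv"
        lyap = pd.read_csv(lyap_path) if lyap_path.exists() else None
        return cls(stride_pairs, lyapunov=lyap, config=config,
                   meta={"source": str(directory)})

    # -- fitting ------------------------------------------------------------

    def _condition_order(self) -> list[str]:
        present = list(dict.fromkeys(self.stride_pairs["condition"]))
        ordered = [c for c in reference.CONDITIONS if c in present]
        return ordered + [c for c in present if c not in ordered]

    def _subject_level(self) -> pd.DataFrame:
        """Subject-level means per (measure, system, condition)."""
        df = self.stride_pairs
        rows = []
        for measure, col in _MEASURE_COLUMN.items():
            for system in SYSTEMS:
                series = df.groupby(["subject", "condition"])[
                    f"{col}_{system}"].mean()
                for (subj, cond), val in series.items():
                    rows.append((measure, system, subj, cond, val))
        # RMS variability of the two step-placement measures
        for base in ("step_width", "step_length"):
            for system in SYSTEMS:
                grp = df.groupby(["subject", "condition", "trial"])[
                    f"{base}_{system}"]
                rms = grp.apply(lambda v: rms_variability(v)
                                if v.size >= 2 else np.nan)
                per_subj = rms.groupby(level=[0, 1]).mean()
                for (subj, cond), val in per_subj.items():
                    rows.append((f"{base}_rms", system, subj, cond, val))
        if self.lyapunov is not None and len(self.lyapunov):
            grp = self.lyapunov.groupby(
                ["axis", "system", "subject", "condition"])["exponent"].mean()
            for (axis, system, subj, cond), val in grp.items():
                rows.append((f"{axis}_lyapunov", system, subj, cond, val))
        return pd.DataFrame(
            rows, columns=["measure", "system", "subject", "condition",
                           "value"])

    def fit(self) -> "StudyResults":
        df = self.stride_pairs
        if df.empty:
            raise GaitStabError("no paired strides to analyze")
        conditions = self._condition_order()
        subject_level = self._subject_level()
        n_subjects = df["subject"].nunique()
        notices = list(self.notices)

        # ---- group summary + repeated-measures ANOVA ----
        anova: dict[tuple[str, str], AnovaResult] = {}
        summary_rows = []
        for (measure, system), sub in subject_level.groupby(
                ["measure", "system"], sort=False):
            pivot = sub.pivot_table(index="subject", columns="condition",
                                    values="value")
            pivot = pivot.reindex(columns=[c for c in conditions
                                           if c in pivot.columns])
            res = None
            if n_subjects < 2:
                if (measure, system) == (next(iter(_MEASURE_COLUMN)),
                                         SYSTEMS[0]):
                    notices.append(
                        "insufficient subjects: ANOVA stage skipped (n=1)")
            elif pivot.shape[1] < 2:
                notices.append(
                    f"{measure}/{system}: fewer than 2 conditions; "
                    "ANOVA skipped")
            elif pivot.isna().any().any():
                notices.append(
                    f"{measure}/{system}: incomplete subject x condition "
                    "table; ANOVA skipped")
            else:
                res = rm_anova_with_posthoc(
                    pivot, control=self.config.control_condition,
                    alpha=self.config.alpha)
                anova[(measure, system)] = res
            for cond in pivot.columns:
                vals = pivot[cond].dropna()
                p_adj = np.nan
                sig = False
                if res is not None and res.posthoc is not None:
                    hit = res.posthoc[res.posthoc["condition"] == cond]
                    if len(hit):
                        p_adj = float(hit["p_adj"].iloc[0])
                        sig = bool(hit["significant"].iloc[0])
                summary_rows.append({
                    "measure": measure, "system": system, "condition": cond,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "n_subjects": int(len(vals)),
                    "p_anova": res.p_value if res is not None else np.nan,
                    "p_posthoc_adj": p_adj,
                    "significant_vs_control": sig,
                })
        summary_frame = pd.DataFrame(summary_rows)

        # ---- Bland-Altman (pooled matched strides) ----
        ba: dict[str, AgreementResult] = {}
        agreement_rows = []
        for measure in PAIRED_MEASURES:
            col = _MEASURE_COLUMN[measure]
            sub = df.dropna(subset=[f"{col}_reference", f"{col}_degraded"])
            res = bland_altman(sub[f"{col}_reference"],
                               sub[f"{col}_degraded"],
                               subjects=sub["subject"],
                               multiplier=self.config.loa_multiplier)
            ba[measure] = res
            agreement_rows.append({
                "measure": measure, "n": res.n, "bias": res.bias,
                "sd": res.sd, "loa_low": res.loa_low,
                "loa_high": res.loa_high, "loa_width": res.loa_width})
        agreement_frame = pd.DataFrame(agreement_rows)

        # ---- ICC(A,1) per condition and pooled ----
        icc: dict[tuple[str, str], ICCResult] = {}
        icc_rows = []
        for measure in PAIRED_MEASURES:
            col = _MEASURE_COLUMN[measure]
            for cond in [*conditions, "overall"]:
                sub = df if cond == "overall" else df[df["condition"] == cond]
                sub = sub.dropna(subset=[f"{col}_reference",
                                         f"{col}_degraded"])
                mat = sub[[f"{col}_reference", f"{col}_degraded"]].to_numpy()
                try:
                    res = icc_a1(mat)
                except (UndefinedICCError, GaitStabError) as exc:
                    notices.append(f"ICC {measure}/{cond}: {exc}")
                    continue
                icc[(measure, cond)] = res
                icc_rows.append({
                    "measure": measure, "condition": cond, "icc": res.icc,
                    "band": res.band, "n_strides": res.n})
        icc_frame = pd.DataFrame(icc_rows)

        provenance = {
            "config_hash": self.config.hash(),
            "config": asdict(self.config),
            **{k: v for k, v in self.meta.items()},
        }
        return StudyResults(
            model=self,
            summary_frame=summary_frame,
            agreement_frame=agreement_frame,
            icc_frame=icc_frame,
            anova=anova,
            bland_altman_results=ba,
            icc_results=icc,
            subject_level=subject_level,
            notices=notices,
            provenance=provenance,
        )


@dataclass
class StudyResults:
    """Fitted study: summary, agreement and reliability tables + diagnostics."""

    model: GaitStabilityStudy
    summary_frame: pd.DataFrame
    agreement_frame: pd.DataFrame
    icc_frame: pd.DataFrame
    anova: dict
    bland_altman_results: dict
    icc_results: dict
    subject_level: pd.DataFrame
    notices: list[str]
    provenance: dict

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = ["Gait-stability two-system agreement study", "=" * 42, ""]
        lines.append(f"Paired strides: {len(self.model.stride_pairs)}; "
                     f"subjects: "
                     f"{self.model.stride_pairs['subject'].nunique()}")
        lines.append("")
        lines.append("Group summary (mean +/- s.d. across subjects; * = "
                     "omnibus p < alpha, + = vs control):")
        conditions = [c for c in
                      dict.fromkeys(self.summary_frame['condition'])]
        header = f"{'measure':<17}{'system':<11}" + "".join(
            f"{c:>17}" for c in conditions) + f"{'p':>10}"
        lines.append(header)
        for (measure, system), sub in self.summary_frame.groupby(
                ["measure", "system"], sort=False):
            cells = []
            for cond in conditions:
                row = sub[sub["condition"] == cond]
                if not len(row):
                    cells.append(f"{'-':>17}")
                    continue
                r = row.iloc[0]
                star = "+" if r["significant_vs_control"] else " "
                cells.append(f"{r['mean']:>8.3f}±{r['sd']:<6.3f}{star:<2}")
            p = sub["p_anova"].iloc[0]
            ptxt = f"{p:>9.2g}" if np.isfinite(p) else "      n/a"
            star = "*" if np.isfinite(p) and p < self.model.config.alpha \
                else " "
            lines.append(f"{measure:<17}{system:<11}" + "".join(cells)
                         + ptxt + star)
        lines.append("")
        lines.append("Bland-Altman (reference - degraded):")
        for _, r in self.agreement_frame.iterrows():
            lines.append(
                f"  {r['measure']:<13} bias {r['bias']:+.3f}   "
                f"LoA [{r['loa_low']:+.3f}, {r['loa_high']:+.3f}]   "
                f"width {r['loa_width']:.3f}   n={int(r['n'])}")
        lines.append("")
        lines.append("ICC(A,1) reliability:")
        pivot = self.icc_frame.pivot_table(index="measure",
                                           columns="condition", values="icc")
        cols = [c for c in [*conditions, "overall"] if c in pivot.columns]
        lines.append(f"  {'measure':<13}" + "".join(f"{c:>13}" for c in cols))
        for measure in PAIRED_MEASURES:
            if measure not in pivot.index:
                continue
            vals = "".join(
                f"{pivot.loc[measure, c]:>13.2f}" if np.isfinite(
                    pivot.loc[measure].get(c, np.nan)) else f"{'-':>13}"
                for c in cols)
            lines.append(f"  {measure:<13}" + vals)
        if self.notices:
            lines.append("")
            lines.append("Notices:")
            lines.extend(f"  - {n}" for n in self.notices)
        return "\n".join(lines)

    def to_csv(self, outdir) -> None:
        """Write stride table, report tables and provenance (deterministic)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.model.stride_pairs.to_csv(outdir / "stride_table.csv",
                                       index=False, float_format=fmt)
        if self.model.lyapunov is not None:
            self.model.lyapunov.to_csv(outdir / "lyapunov.csv", index=False,
                                       float_format=fmt)
        self.summary_frame.to_csv(outdir / "summary.csv", index=False,
                                  float_format=fmt)
        self.agreement_frame.to_csv(outdir / "bland_altman.csv", index=False,
                                    float_format=fmt)
        self.icc_frame.to_csv(outdir / "icc.csv", index=False,
                              float_format=fmt)
        with open(outdir / "provenance.json", "w") as fh:
            json.dump({**self.provenance, "notices": self.notices}, fh,
                      indent=2, sort_keys=True, default=str)

    # -- plotting -----------------------------------------------------------

    def plot_bland_altman(self, measure: str, ax=None):
        """Scatter of between-system differences vs pair means with LoA."""
        import matplotlib.pyplot as plt

        res = self.bland_altman_results[measure]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(res.means, res.differences, s=6, alpha=0.5)
        ax.axhline(res.bias, color="k", lw=1.5)
        for y in (res.loa_low, res.loa_high):
            ax.axhline(y, color="k", ls="--", lw=1)
        ax.set_xlabel(f"mean {measure}")
        ax.set_ylabel("reference - degraded")
        ax.set_title(f"Bland-Altman: {measure}")
        return ax

    def plot_icc_scatter(self, measure: str, ax=None):
        """Degraded-vs-reference stride scatter with the identity line."""
        import matplotlib.pyplot as plt

        col = _MEASURE_COLUMN[measure]
        df = self.model.stride_pairs
        if ax is None:
            _, ax = plt.subplots()
        for cond, sub in df.groupby("condition"):
            ax.scatter(sub[f"{col}_degraded"], sub[f"{col}_reference"],
                       s=6, alpha=0.5, label=cond)
        lims = np.array(ax.get_xlim())
        ax.plot(lims, lims, "k:", lw=1)
        ax.set_xlabel(f"{measure} (degraded)")
        ax.set_ylabel(f"{measure} (reference)")
        ax.legend(fontsize=8)
        return ax


def run_study(
    spec: StudySpec | None = None,
    config: AnalysisConfig | None = None,
    outdir=None,
) -> StudyResults:
    """Generate (or default) a synthetic study, fit it, optionally write CSVs."""
    model = GaitStabilityStudy.from_synthetic(spec, config)
    results = model.fit()
    if outdir is not None:
        results.to_csv(outdir)
    return results
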