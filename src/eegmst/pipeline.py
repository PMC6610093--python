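"""End-to-end cohort pipeline: recordings -> connectivity -> trees ->
reaction-time decomposition -> group statistics.

The per-subject chain is the one applied to every participant of a
resting-state study: common-average re-reference, band-pass into the six
analysis bands, thirty 4096-sample epochs, a PLI matrix per epoch, a
maximum spanning tree per matrix, and tree metrics averaged across
epochs. The group layer compares log-transformed metrics between groups
by ANCOVA with Bonferroni control, then correlates group-separating
metrics with the ex-Gaussian RT parameters inside the patient group.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .connectivity import average_matrices, epochs_pli, global_pli
from .exgauss import ExGaussianModel, summary_stats
from .preprocess import (BandSet, DEFAULT_EPOCH_LEN, DEFAULT_N_EPOCHS,
                         preprocess_subject)
from .stats import (CORRELATION_ALPHA, ancova_group_effect, bonferroni,
                    correlate, log_transform)
from .tree import (MSTMetrics, RegionConfig, average_metrics,
                   max_spanning_tree, tree_metrics)

logger = logging.getLogger("eegmst")

#: Tree/connectivity quantities reported per band, in report order.
REPORTED_METRICS = ("pli", "diameter", "leaf_fraction", "degree_correlation",
                    "bc_max", "bc_global", "bc_anterior", "bc_posterior")

#: Cognitive outcomes compared between groups.
COGNITIVE_OUTCOMES = ("n_stimuli", "n_errors", "rt_mean", "isd",
                      "mu", "sigma", "tau")


@dataclass
class SubjectData:
    """One participant's inputs: a recording and a reaction-time sample."""

    subject_id: str
    group: str
    recording: "eio.EEGRecording | str | Path"
    rts: "np.ndarray | str | Path | None" = None
    covariates: dict[str, float] = field(default_factory=dict)

    def load_recording(self) -> eio.EEGRecording:
        if isinstance(self.recording, eio.EEGRecording):
            return self.recording
        return eio.read_recording(self.recording)

    def load_rts(self) -> np.ndarray | None:
        if self.rts is None:
            return None
        if isinstance(self.rts, (str, Path)):
            df = pd.read_csv(self.rts)
            col = "rt_ms" if "rt_ms" in df.columns else df.columns[-1]
            return df[col].to_numpy(dtype=float)
        return np.asarray(self.rts, dtype=float)


def analyze_subject_bands(
    rec: eio.EEGRecording,
    bands: BandSet | None = None,
    regions: RegionConfig | None = None,
    epoch_len: int = DEFAULT_EPOCH_LEN,
    n_epochs: int = DEFAULT_N_EPOCHS,
    car: bool = True,
) -> dict[str, tuple[float, MSTMetrics]]:
    """Per band: grand-mean PLI and epoch-averaged tree metrics.

    ``car=False`` skips common-average re-referencing (appropriate for
    synthetic sensor-space recordings; see ``preprocess_subject``).
    """
    out: dict[str, tuple[float, MSTMetrics]] = {}
    for band, epochs in preprocess_subject(rec, bands=bands,
                                           epoch_len=epoch_len,
                                           n_epochs=n_epochs,
                                           car=car).items():
        mats = epochs_pli(epochs)
        gp = global_pli(average_matrices(mats))
        per_epoch = [tree_metrics(max_spanning_tree(m), regions) for m in mats]
        out[band] = (gp, average_metrics(per_epoch))
    return out


def build_cohort_table(
    subjects: list[SubjectData],
    bands: BandSet | None = None,
    regions: RegionConfig | None = None,
    epoch_len: int = DEFAULT_EPOCH_LEN,
    n_epochs: int = DEFAULT_N_EPOCHS,
    car: bool = True,
) -> pd.DataFrame:
    """One row per subject: network metrics per band, RT measures,
    clinical covariates. Column names are ``<metric>_<band>``."""
    rows = []
    for subj in subjects:
        t0 = time.perf_counter()
        row: dict[str, object] = {"subject": subj.subject_id,
                                  "group": subj.group, **subj.covariates}
        try:
            rec = subj.load_recording()
            per_band = analyze_subject_bands(rec, bands=bands, regions=regions,
                                             epoch_len=epoch_len,
                                             n_epochs=n_epochs, car=car)
        except Exception as err:
            raise RuntimeError(
                f"[network stage] subject {subj.subject_id}: {err}") from err
        for band, (gp, metrics) in per_band.items():
            row[f"pli_{band}"] = gp
            for name, value in metrics.as_dict().items():
                row[f"{name}_{band}"] = value
        rts = subj.load_rts()
        if rts is not None:
            try:
                row.update(summary_stats(rts))
                fit = ExGaussianModel(rts).fit()
                row.update(mu=fit.mu, sigma=fit.sigma, tau=fit.tau,
                           exgauss_converged=fit.converged)
            except Exception as err:
                raise RuntimeError(
                    f"[RT stage] subject {subj.subject_id}: {err}") from err
        logger.info("subject %s analysed in %.2f s", subj.subject_id,
                    time.perf_counter() - t0)
        rows.append(row)
    return pd.DataFrame(rows)


def _available(table: pd.DataFrame, cols) -> list[str]:
    return [c for c in cols if c in table.columns and
            table[c].notna().sum() > 0]


def group_report(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "education", "premorbid_iq"),
    patient_group: str | None = None,
    log_metrics: bool = True,
) -> dict[str, pd.DataFrame]:
    """Group comparison and brain-behaviour correlation report.

    Returns tidy frames: ``network`` (per band-metric ANCOVA with partial
    eta squared and Bonferroni-adjusted p over the whole metric family),
    ``cognitive`` (the RT/ex-Gaussian comparison), and ``correlations``
    (Pearson r of each group-separating network metric with mu and tau
    inside the patient group, significant at p < 0.01).
    """
    groups = sorted(table["group"].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"group report needs exactly 2 groups, got {groups}")
    if patient_group is None:
        patient_group = "SZ" if "SZ" in groups else groups[0]
    usable_cov = _available(table, covariates)

    metric_cols = [c for c in table.columns
                   if any(c.startswith(m + "_") for m in REPORTED_METRICS)
                   and not c.startswith("diameter_norm")]
    net_rows = []
    for col in metric_cols:
        values = table[col]
        model_col = col
        work = table.copy()
        if log_metrics:
            # degree correlation may be negative; log only nonnegative metrics
            if (values.dropna() >= 0).all():
                work[col + "_log"] = log_transform(values.fillna(np.nan))
                model_col = col + "_log"
        try:
            eff = ancova_group_effect(work, model_col, covariates=tuple(usable_cov))
        except ValueError as err:
            logger.warning("skipping %s: %s", col, err)
            continue
        net_rows.append({
            "metric": col, "F": eff.f, "df1": eff.df[0], "df2": eff.df[1],
            "p": eff.p, "eta_p_sq": eff.eta_p_sq, "direction": eff.direction,
            "n": eff.n_used,
        })
    network = pd.DataFrame(net_rows)
    if len(network):
        network["p_bonferroni"] = bonferroni(network["p"], m=len(network))
        network["significant"] = network["p_bonferroni"] < 0.05

    cog_rows = []
    for col in _available(table, COGNITIVE_OUTCOMES):
        try:
            eff = ancova_group_effect(table, col, covariates=tuple(usable_cov))
        except ValueError as err:
            logger.warning("skipping %s: %s", col, err)
            continue
        cog_rows.append({
            "outcome": col, "F": eff.f, "df1": eff.df[0], "df2": eff.df[1],
            "p": eff.p, "eta_p_sq": eff.eta_p_sq, "direction": eff.direction,
            "n": eff.n_used,
        })
    cognitive = pd.DataFrame(cog_rows)
    if len(cognitive):
        cognitive["p_bonferroni"] = bonferroni(cognitive["p"],
                                               m=len(cognitive))
        cognitive["significant"] = cognitive["p_bonferroni"] < 0.05

    corr_rows = []
    patients = table[table["group"] == patient_group]
    sep = (network[network["significant"]]["metric"].tolist()
           if len(network) else [])
    for col in sep:
        for param in ("mu", "tau"):
            if param not in patients.columns or \
                    patients[param].notna().sum() < 4:
                continue
            try:
                r, p = correlate(patients[col], patients[param])
            except ValueError:
                continue
            corr_rows.append({"metric": col, "rt_parameter": param,
                              "r": r, "p": p,
                              "significant": p < CORRELATION_ALPHA})
    correlations = pd.DataFrame(corr_rows)
    return {"network": network, "cognitive": cognitive,
            "correlations": correlations}


def run_group_pipeline(
    subjects: list[SubjectData],
    bands: BandSet | None = None,
    regions: RegionConfig | None = None,
    covariates: tuple[str, ...] = ("age", "education", "premorbid_iq"),
    patient_group: str | None = None,
    epoch_len: int = DEFAULT_EPOCH_LEN,
    n_epochs: int = DEFAULT_N_EPOCHS,
    car: bool = True,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline for a cohort.

    Returns ``{"cohort": per-subject table, "network": ..., "cognitive":
    ..., "correlations": ...}``; with fewer than two subjects per group
    the group layer is skipped with a warning and only the per-subject
    table is returned. When ``out_dir`` is given every frame is written
    as CSV there.
    """
    t0 = time.perf_counter()
    table = build_cohort_table(subjects, bands=bands, regions=regions,
                               epoch_len=epoch_len, n_epochs=n_epochs, car=car)
    report: dict[str, pd.DataFrame] = {"cohort": table}
    counts = table["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        warnings.warn("fewer than 2 subjects per group: group statistics "
                      "skipped; per-subject metrics returned", stacklevel=2)
    else:
        report.update(group_report(table, covariates=covariates,
                                   patient_group=patient_group))
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in report.items():
            frame.to_csv(out_dir / f"{name}.csv", index=False)
    return report


def load_config(path: str | Path) -> list[SubjectData]:
    """Read a cohort description from JSON/YAML.

    Expected layout::

        subjects:
          - subject_id: SZ001
            group: SZ
            recording: path/to/rec.edf   # or .txt ASCII matrix
            rts: path/to/rts.csv
            age: 21
            education: 13
            premorbid_iq: 108
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    base = path.parent
    subjects = []
    for entry in cfg["subjects"]:
        entry = dict(entry)
        sid = entry.pop("subject_id")
        group = entry.pop("group")
        rec = entry.pop("recording")
        rts = entry.pop("rts", None)
        subjects.append(SubjectData(
            subject_id=sid, group=group,
            recording=base / rec,
            rts=None if rts is None else base / rts,
            covariates={k: float(v) for k, v in entry.items()},
        ))
    return subjects
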