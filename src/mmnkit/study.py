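"""End-to-end study orchestration.

``run_study`` drives the full chain for every subject and condition —
simulate (or load), preprocess, derive the MMN difference wave, measure
peak latency / mean amplitude, build topographic maps — then runs the
group statistics: stimulus-type x gender ANOVAs on window amplitudes per
condition, condition x gender ANOVAs on the MMN measures, post hoc
t-tests, and the DISS randomization test per condition. The report carries
per-stage trial counts, a 2 x 2 cell summary, every test result and full
provenance (config hash + seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures as ms
from . import preprocess as pp
from . import stats as st
from . import topo
from .io import config_hash
from .simulate import StudyConfig, StudyDataset, generate_study

log = logging.getLogger(__name__)


@dataclass
class RunReport:
    counts: pd.DataFrame            # subject x condition trial bookkeeping
    measures: pd.DataFrame          # tidy per-subject MMN measures
    cell_summary: pd.DataFrame      # gender x condition means and SEMs
    anovas: dict[str, st.AnovaTable]
    ttests: dict[str, st.TestResult]
    diss: dict[str, topo.DissResult]
    config_hash: str
    seed: int | None
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def anova_dict(a: st.AnovaTable) -> dict:
            return {
                e.name: {"SS": e.ss, "df1": e.df_num, "df2": e.df_den,
                         "F": e.F, "p": e.p, "eta_p2": e.eta_p2}
                for e in a.effects.values()
            }

        return {
            "provenance": {"config_hash": self.config_hash, "seed": self.seed},
            "counts": self.counts.to_dict(orient="records"),
            "cell_summary": self.cell_summary.to_dict(orient="records"),
            "measures": self.measures.to_dict(orient="records"),
            "anovas": {k: anova_dict(v) for k, v in self.anovas.items()},
            "ttests": {
                k: {"t": v.t, "df": v.df, "p": v.p, "d": v.d, "kind": v.kind}
                for k, v in self.ttests.items()
            },
            "diss": {
                k: {"diss": v.diss_observed, "p": v.p_value,
                    "n_permutations": v.n_permutations, "seed": v.seed}
                for k, v in self.diss.items()
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = ["Study report", "============", "", "Cell summary:"]
        lines.append(self.cell_summary.to_string(index=False))
        for name, a in self.anovas.items():
            lines.append("")
            lines.append(f"[{name}] " + a.summary())
        lines.append("")
        for name, t in self.ttests.items():
            lines.append(f"{name}: {t.summary()}")
        lines.append("")
        for name, d in self.diss.items():
            lines.append(f"DISS {name}: {d.summary()}")
        return "\n".join(lines)


def cell_summary_table(measures: pd.DataFrame) -> pd.DataFrame:
    """Gender x condition means and SEMs of amplitude and latency."""
    rows = []
    for (cond, gender), grp in measures.groupby(["condition", "gender"]):
        n = len(grp)
        rows.append({
            "condition": cond, "gender": gender, "n": n,
            "mean_amplitude_uv": grp["mean_amplitude_uv"].mean(),
            "mean_amplitude_sem": grp["mean_amplitude_uv"].std(ddof=1) / np.sqrt(n),
            "peak_latency_ms": grp["peak_latency_ms"].mean(),
            "peak_latency_sem": grp["peak_latency_ms"].std(ddof=1) / np.sqrt(n),
        })
    return pd.DataFrame(rows)


def _measure_one(std_set, dev_set, subject_id, prep_cfg):
    """Preprocess both epoch sets and derive measures for one subject/condition."""
    std_p = pp.preprocess_epochs(std_set, prep_cfg)
    dev_p = pp.preprocess_epochs(dev_set, prep_cfg)
    std_ev = ms.average_evoked(std_p, "standard")
    dev_ev = ms.average_evoked(dev_p, "deviant")
    if std_set.condition == "pattern":
        dw = ms.pattern_mmn(std_ev, dev_ev)
    else:
        dw = ms.simple_mmn(std_ev, dev_ev)
    measure = ms.measure_mmn(dw, subject_id)
    tmap = topo.subject_topomap(dw, measure)
    amp_std = ms.window_mean(std_ev, measure.electrode, measure.window_ms)
    amp_dev = ms.window_mean(dev_ev, measure.electrode, measure.window_ms)
    counts = {
        "presented": std_p.n_trials + dev_p.n_trials,
        "retained": std_p.n_retained + dev_p.n_retained,
        "rejected": int(std_p.rejected.sum() + dev_p.rejected.sum()),
    }
    return measure, tmap, amp_std, amp_dev, counts


def run_study(data: StudyDataset | StudyConfig,
              prep: pp.PreprocessConfig | None = None,
              n_permutations: int = 10_000,
              seed: int | None = None,
              out_dir: str | Path | None = None) -> RunReport:
    """Run the full analysis over a study.

    ``data`` is either a StudyConfig (a study is simulated from it) or any
    dataset object exposing ``subject_ids``, ``genders()``,
    ``subject_epochs(subject, condition)`` and ``conditions``.
    Deterministic given data, config and seed; ``seed`` feeds the DISS
    permutation tests (and the simulation when a config with no explicit
    seed change is passed).
    """
    t0 = time.time()
    stage_seconds: dict[str, float] = {}
    if isinstance(data, StudyConfig):
        if seed is not None:
            data.seed = seed
        dataset = generate_study(data)
        chash = config_hash(
            {"n_female": data.n_female, "n_male": data.n_male,
             "sampling_rate_hz": data.sampling_rate_hz,
             "noise_sd_uv": data.noise_sd_uv,
             "artifact_trial_fraction": data.artifact_trial_fraction,
             "n_deviants": data.n_deviants, "p_deviant": data.p_deviant,
             "soa_ms": data.soa_ms, "seed": data.seed}
        )
        seed = data.seed
        conditions = data.conditions
    else:
        dataset = data
        conditions = tuple(getattr(dataset, "conditions", ("simple", "pattern")))
        chash = config_hash({"subjects": list(dataset.subject_ids),
                             "conditions": list(conditions)})
    prep_cfg = prep or pp.PreprocessConfig()
    genders = dataset.genders()

    all_measures: list[ms.MMNMeasure] = []
    maps: dict[str, dict[str, topo.TopoMap]] = {c: {} for c in conditions}
    stim_rows: list[dict] = []
    count_rows: list[dict] = []
    for sid in dataset.subject_ids:
        for cond in conditions:
            t_sub = time.time()
            try:
                std_set, dev_set = dataset.subject_epochs(sid, cond)
                measure, tmap, amp_std, amp_dev, counts = _measure_one(
                    std_set, dev_set, sid, prep_cfg
                )
            except Exception as err:
                raise RuntimeError(
                    f"stage failed for subject {sid!r}, condition {cond!r}: {err}"
                ) from err
            all_measures.append(measure)
            maps[cond][sid] = tmap
            stim_rows += [
                {"subject_id": sid, "gender": genders[sid], "condition": cond,
                 "stimulus": "standard", "window_amp_uv": amp_std},
                {"subject_id": sid, "gender": genders[sid], "condition": cond,
                 "stimulus": "deviant", "window_amp_uv": amp_dev},
            ]
            count_rows.append({"subject_id": sid, "condition": cond, **counts})
            log.info("subject %s / %s done in %.1fs (retained %d/%d)",
                     sid, cond, time.time() - t_sub,
                     counts["retained"], counts["presented"])
    stage_seconds["pipeline"] = time.time() - t0

    measures_df = ms.measures_to_frame(all_measures, genders)
    counts_df = pd.DataFrame(count_rows)
    stim_df = pd.DataFrame(stim_rows)
    summary_df = cell_summary_table(measures_df)

    t1 = time.time()
    anovas: dict[str, st.AnovaTable] = {}
    ttests: dict[str, st.TestResult] = {}
    two_genders = len(set(genders.values())) == 2 and \
        min(pd.Series(genders).value_counts()) >= 2
    if two_genders:
        for cond in conditions:
            sub = stim_df[stim_df["condition"] == cond]
            anovas[f"stimulus_x_gender[{cond}]"] = st.mixed_anova_2x2(
                sub, dv="window_amp_uv", within="stimulus", between="gender"
            )
        if len(conditions) == 2:
            for dv, tag in (("mean_amplitude_uv", "amplitude"),
                            ("peak_latency_ms", "latency")):
                anovas[f"condition_x_gender[{tag}]"] = st.mixed_anova_2x2(
                    measures_df, dv=dv, within="condition", between="gender"
                )
            piv = measures_df.pivot_table(index=["subject_id", "gender"],
                                          columns="condition",
                                          values="peak_latency_ms",
                                          aggfunc="first").reset_index()
            for gender in sorted(piv["gender"].unique()):
                g = piv[piv["gender"] == gender]
                ttests[f"paired_latency[{gender}]"] = st.paired_t(
                    g[conditions[0]], g[conditions[1]],
                    kind_note=f"{conditions[0]} vs {conditions[1]}",
                )
        for cond in conditions:
            sub = measures_df[measures_df["condition"] == cond]
            f = sub[sub["gender"] == "female"]["peak_latency_ms"]
            m = sub[sub["gender"] == "male"]["peak_latency_ms"]
            ttests[f"gender_latency[{cond}]"] = st.independent_t(
                f, m, kind_note="female vs male"
            )
    else:
        log.warning("fewer than 2 subjects in a gender group: "
                    "group statistics skipped")

    diss_results: dict[str, topo.DissResult] = {}
    if two_genders:
        rng = np.random.default_rng(seed)
        for cond in conditions:
            fa = [maps[cond][s] for s in dataset.subject_ids
                  if genders[s] == "female"]
            mb = [maps[cond][s] for s in dataset.subject_ids
                  if genders[s] == "male"]
            diss_results[cond] = topo.diss_permutation_test(
                fa, mb, n_permutations=n_permutations,
                seed=int(rng.integers(2 ** 31)),
            )
    stage_seconds["statistics"] = time.time() - t1

    report = RunReport(
        counts=counts_df, measures=measures_df, cell_summary=summary_df,
        anovas=anovas, ttests=ttests, diss=diss_results,
        config_hash=chash, seed=seed, stage_seconds=stage_seconds,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for df, name in ((measures_df, "measures.csv"),
                         (counts_df, "counts.csv"),
                         (summary_df, "cell_summary.csv"),
                         (stim_df, "window_amplitudes.csv")):
            df.assign(config_hash=chash, seed=seed).to_csv(out / name,
                                                           index=False)
        for cond, res in diss_results.items():
            pd.DataFrame({"diss_null": res.null_distribution}).to_csv(
                out / f"diss_null_{cond}.csv", index=False
            )
        map_rows = [
            {"subject_id": sid, "condition": cond, "electrode": lbl, "value": v}
            for cond in conditions
            for sid, tm in maps[cond].items()
            for lbl, v in zip(tm.labels, tm.values)
        ]
        pd.DataFrame(map_rows).to_csv(out / "topomaps.csv", index=False)
        report.to_json(out / "report.json")
    return report
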