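"""Self-contained reproduction experiments on the calibrated synthetic cohort.

Each function regenerates its inputs from a seed and runs the actual analysis
code (no cached values), returning the quantities the study design is built
around: caudate group means after the full simulate-fit-aggregate pipeline,
the severity rank-correlation in the internal medullary lamina, and the
ANCOVA severity slope.  They are used by the acceptance script and the test
suite, and are convenient entry points for power or sensitivity studies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import roi_pipeline as roi
from . import stats as st
from . import synthetic_data as sd
from . import zspectrum_fitting as zf
from .atlas import CSF_CODE


def caudate_recovery_experiment(seed: int, n_pwpd: int = 25, n_hc: int = 24,
                                blob_shape: tuple = (5, 6, 7),
                                plof_cfg: zf.PLOFConfig | None = None) -> dict:
    """Full pipeline on a caudate-only reduced phantom cohort.

    Simulates the default cohort, synthesizes per-voxel spectra for a
    caudate-only phantom (both hemispheres, ~2 x prod(blob_shape) voxels per
    subject), runs voxel-wise PLOF, aggregates with the hemisphere rule and
    Tukey filtering, and returns cohort means and the group tests for both
    channels.
    """
    cohort = sd.simulate_clinical_cohort(n_pwpd, n_hc, seed)
    acq = sd.AcquisitionConfig()
    eff = sd.EffectConfig()
    plof_cfg = plof_cfg or zf.PLOFConfig()

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subject, (sid, ph) in zip(
                cohort, sd.iter_phantoms(cohort, eff, acq, seed,
                                         regions=("Ca",), blob_shape=blob_shape)):
            mask = (ph.label_volume > 0) & (ph.label_volume != CSF_CODE)
            maps = zf.fit_map(ph.cest_4d, acq.offsets_ppm, mask, plof_cfg)
            conv = maps["converged"].astype(bool)
            for metric in ("guan_pct", "amide_pct"):
                per_hemi = roi.extract_roi_means(maps[metric], ph.label_volume,
                                                 ["Ca"], qc_mask=conv,
                                                 subject_id=sid)
                combined = roi.hemisphere_select(per_hemi, subject.group,
                                                 subject.affected_side)
                combined["metric"] = metric
                combined["group"] = subject.group
                rows.append(combined)
    table = pd.concat(rows, ignore_index=True)

    out = {}
    for metric in ("guan_pct", "amide_pct"):
        sub = table[table.metric == metric].copy()
        groups = dict(zip(sub.subject_id, sub.group))
        sub = roi.filter_region_table(sub.drop(columns="group"), groups)
        sub["group"] = sub.subject_id.map(groups)
        ok = sub[~sub.excluded]
        hc = ok[ok.group == "HC"].value_pct.to_numpy()
        pwpd = ok[ok.group == "PwPD"].value_pct.to_numpy()
        key = metric.replace("_pct", "")
        out[f"hc_{key}_mean"] = float(hc.mean()) if hc.size else float("nan")
        out[f"pwpd_{key}_mean"] = float(pwpd.mean()) if pwpd.size else float("nan")
        if hc.size >= 2 and pwpd.size >= 2:
            t = st.two_sample_ttest(hc, pwpd)
            out[f"{key}_p"] = t.p_two_sided
        out[f"n_hc_{key}"] = int(hc.size)
        out[f"n_pwpd_{key}"] = int(pwpd.size)
    return out


def severity_kendall_experiment(seed: int, n_patients: int = 2500,
                                region: str = "TH-IML") -> dict:
    """Kendall tau-b between region signal and motor score in a copula-mode
    patient sample (region-value level, no imaging)."""
    eff = sd.EffectConfig(association_mode="copula")
    sample = sd.severity_association_sample(region, n_patients, eff, seed)
    k = st.kendall_tau_b(sample.guan_pct.to_numpy(), sample.updrs3.to_numpy())
    return {"tau_b": k.tau_b, "p": k.p_value, "n": k.n}


def ancova_slope_experiment(seed: int, n_patients: int = 2000,
                            region: str = "TH-IML") -> dict:
    """ANCOVA severity coefficient recovered from a linear-mode patient
    cohort (region-value level, no imaging)."""
    cohort = sd.simulate_clinical_cohort(n_patients, 0, seed)
    eff = sd.EffectConfig(association_mode="linear")
    table = sd.simulate_region_table(cohort, [region], eff, seed)
    a = st.ancova_fit(table.guan_pct.to_numpy(), table.updrs3.to_numpy(),
                      table.age_years.to_numpy(), list(table.sex))
    return {"beta_severity": float(a.params["severity"]),
            "p_severity": float(a.pvalues["severity"]), "n": a.n}
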