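"""End-to-end orchestration: per-sample stage execution, hydration-series
assembly, dome detection, and a provenance-carrying JSON report.

A study is described by a configuration (plain nested dict, typically
loaded from YAML): a list of samples, each with a wt % water label and,
per stage, either an input file or a synthetic-generation recipe.  Stage
failures are collected per sample instead of aborting the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from . import assays, cd, hydration, sans, synthetic, thermal, uvvis
from .exceptions import DesfoldError
from . import io as dio
from .units import celsius_to_kelvin

STAGES = ("uvvis", "fluor", "cd", "thermal", "sans", "assay")

DEFAULT_TREF_CELSIUS = 63.2


@dataclass
class AnalysisReport:
    samples: dict = field(default_factory=dict)  # label -> {stage: result dict}
    series: dict = field(default_factory=dict)  # observable -> dome summary
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        def _default(o):
            if isinstance(o, np.bool_):
                return bool(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(
            {"samples": self.samples, "series": self.series, "provenance": self.provenance},
            indent=indent, sort_keys=True, default=_default,
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(samples=d["samples"], series=d["series"], provenance=d["provenance"])


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(base_seed: int, label: str, stage: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{label}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _resolve_input(spec: dict, stage: str, seed: int, base: Path, digests: dict):
    """A stage input is either {"file": path, ...} or {"synthetic": {params}}."""
    if "file" in spec:
        path = base / spec["file"]
        digests[str(path)] = _digest(path)
        return ("file", path)
    if "synthetic" in spec:
        params = dict(spec["synthetic"])
        params.setdefault("seed", seed)
        return ("synthetic", params)
    raise DesfoldError(f"stage {stage!r}: specify either 'file' or 'synthetic'")


def _run_uvvis(spec, seed, base, digests) -> dict:
    kind, src = _resolve_input(spec, "uvvis", seed, base, digests)
    if kind == "file":
        s = dio.read_spectrum(src, kind="absorbance")
    else:
        s, _ = synthetic.gen_absorbance(**src)
    d2 = uvvis.second_derivative(s, spec.get("window_points", 9), spec.get("poly_order", 3))
    p = uvvis.tyr_trp_parameters(d2, mode=spec.get("amplitude_mode", "peak_to_trough"))
    return {"lambda_tyr": p.lambda_tyr, "amp_tyr": p.amp_tyr,
            "amp_trp": p.amp_trp, "tyr_trp_ratio": p.ratio}


def _run_fluor(spec, seed, base, digests) -> dict:
    kind, src = _resolve_input(spec, "fluor", seed, base, digests)
    if kind == "file":
        s = dio.read_spectrum(src, kind="emission")
    else:
        s, _ = synthetic.gen_emission(**src)
    window = tuple(spec.get("window", uvvis.CSM_WINDOW))
    summary = uvvis.center_of_spectral_mass(s, window)
    return {"csm": summary.csm, "window": list(summary.window)}


def _run_cd(spec, seed, base, digests) -> dict:
    kind, src = _resolve_input(spec, "cd", seed, base, digests)
    if kind == "file":
        s = dio.read_spectrum(src, kind="mre")
    else:
        params = dict(src)
        fr = params.pop("fractions")
        params["fractions"] = cd.SecondaryStructureFractions(**fr) if isinstance(fr, dict) else fr
        s, _ = synthetic.gen_cd(**params)
    fit_range = tuple(spec.get("fit_range", cd.FIT_RANGE))
    result = cd.deconvolve(s, fit_range=fit_range)
    return {"fractions": result.fractions.as_dict(), "residual_rms": result.residual_rms}


def _run_thermal(spec, seed, base, digests, tref_k: float) -> dict:
    kind, src = _resolve_input(spec, "thermal", seed, base, digests)
    if kind == "file":
        m = dio.read_melting_curve(src, celsius=spec.get("celsius", False))
    else:
        m, _ = synthetic.gen_melt(**src)
    fit = thermal.fit_two_state(m)
    n_trans = thermal.transition_count(fit.fd_curve, m.temperatures)
    return {
        "tm_K": fit.tm, "dh_m_kJ_mol": fit.dh_m,
        "dg_ref_kJ_mol": thermal.delta_g_at(fit, tref_k),
        "t_ref_K": tref_k,
        "transition_count": n_trans,
        "multi_state_flag": fit.multi_state_flag,
        "residual_rms": fit.residual_rms,
    }


def _run_sans(spec, seed, base, digests) -> dict:
    kind, src = _resolve_input(spec, "sans", seed, base, digests)
    if kind == "file":
        profile = dio.read_sas_profile(src, concentration=spec.get("concentration"))
    else:
        profile, _ = synthetic.gen_sans(**src)
    rg_g, i0_g = sans.guinier_fit(profile)
    scan_spec = spec.get("dmax_scan")
    if scan_spec:
        scan = np.linspace(scan_spec[0], scan_spec[1], int(scan_spec[2]) if len(scan_spec) > 2 else 12)
        d_max = sans.choose_dmax(profile, scan).d_max
    else:
        d_max = spec.get("d_max", 4.0 * rg_g)
    pd = sans.ift(profile, d_max)
    conc = profile.concentration or 1.0
    return {
        "guinier_rg_A": rg_g, "guinier_i0": i0_g, "d_max_A": pd.d_max,
        "rg_A": pd.rg, "r1_A": pd.r1, "i0": pd.i0, "i0_per_conc": pd.i0 / conc,
        "fit_chi2": pd.fit_chi2, "alpha": pd.regularization_alpha,
    }


def _run_assay(spec, seed, base, digests) -> dict:
    kind, src = _resolve_input(spec, "assay", seed, base, digests)
    if kind == "file":
        c = dio.read_lysis_curve(src, enzyme_mass=spec.get("enzyme_mass", 1.0))
    else:
        c, _ = synthetic.gen_lysis(**src)
    r = assays.initial_rate(c)
    return {"initial_rate_AU_min": r.rate, "no_lysis": r.no_lysis,
            "specific_activity_IU_mg": assays.specific_activity(c),
            "enzyme_mass_mg": c.enzyme_mass}


#: Observables assembled into hydration series: (stage, key in stage result).
SERIES_OBSERVABLES = {
    "tyr_trp_ratio": ("uvvis", "tyr_trp_ratio"),
    "lambda_tyr": ("uvvis", "lambda_tyr"),
    "csm": ("fluor", "csm"),
    "tm": ("thermal", "tm_K"),
    "dg_ref": ("thermal", "dg_ref_kJ_mol"),
    "d_max": ("sans", "d_max_A"),
    "r1": ("sans", "r1_A"),
    "alpha_fraction": ("cd", None),  # nested under fractions
    "specific_activity": ("assay", "specific_activity_IU_mg"),
}


def run_pipeline(config: dict, base_path: str | Path | None = None) -> AnalysisReport:
    """Execute all configured stages for every sample and assemble the report.

    Per-sample stage failures are recorded under the sample's ``errors``
    key; the run itself always completes.
    """
    base = Path(base_path) if base_path is not None else Path.cwd()
    seed = int(config.get("seed", 0))
    tref_k = celsius_to_kelvin(float(config.get("tref_celsius", DEFAULT_TREF_CELSIUS)))
    digests: dict[str, str] = {}
    report = AnalysisReport()

    for sample in config.get("samples", []):
        label = str(sample["label"])
        wt = float(sample["wt_percent"])
        entry: dict[str, Any] = {
            "wt_percent": wt,
            "regime": hydration.classify_regime(wt),
            "errors": {},
        }
        runners = {
            "uvvis": lambda sp, sd: _run_uvvis(sp, sd, base, digests),
            "fluor": lambda sp, sd: _run_fluor(sp, sd, base, digests),
            "cd": lambda sp, sd: _run_cd(sp, sd, base, digests),
            "thermal": lambda sp, sd: _run_thermal(sp, sd, base, digests, tref_k),
            "sans": lambda sp, sd: _run_sans(sp, sd, base, digests),
            "assay": lambda sp, sd: _run_assay(sp, sd, base, digests),
        }
        for stage in STAGES:
            if stage not in sample:
                continue
            try:
                entry[stage] = runners[stage](sample[stage], _stage_seed(seed, label, stage))
            except Exception as exc:  # collected, not fatal
                entry["errors"][stage] = f"{type(exc).__name__}: {exc}"
        report.samples[label] = entry

    # relative quantities against the configured reference sample
    ref_label = config.get("reference")
    if ref_label and ref_label in report.samples:
        ref = report.samples[ref_label]
        for label, entry in report.samples.items():
            if "sans" in entry and "sans" in ref:
                try:
                    # i0_per_conc already folds in each sample's concentration
                    entry["sans"]["n_agg"] = sans.aggregation_number(
                        entry["sans"]["i0_per_conc"], 1.0, ref["sans"]["i0_per_conc"], 1.0)
                except DesfoldError as e:
                    entry["errors"]["n_agg"] = str(e)
            if "assay" in entry and "assay" in ref and ref["assay"]["specific_activity_IU_mg"] > 0:
                entry["assay"]["relative_activity"] = (
                    entry["assay"]["specific_activity_IU_mg"] / ref["assay"]["specific_activity_IU_mg"]
                )
            if "cd" in entry and "cd" in ref:
                sample_fr = cd.SecondaryStructureFractions(**entry["cd"]["fractions"])
                ref_fr = cd.SecondaryStructureFractions(**ref["cd"]["fractions"])
                entry["cd"]["fold_change"] = {
                    motif: {"value": mc.value, "mode": mc.mode}
                    for motif, mc in cd.fold_change(sample_fr, ref_fr).items()
                }

    # hydration series + dome detection
    for name in config.get("dome_observables", []):
        if name not in SERIES_OBSERVABLES:
            report.series[name] = {"error": f"unknown observable {name!r}"}
            continue
        stage, key = SERIES_OBSERVABLES[name]
        wt_vals, obs_vals = [], []
        for entry in report.samples.values():
            if stage not in entry:
                continue
            value = entry[stage]["fractions"]["alpha"] if key is None else entry[stage].get(key)
            if value is None:
                continue
            wt_vals.append(entry["wt_percent"])
            obs_vals.append(value)
        try:
            series = hydration.HydrationSeries(np.array(wt_vals), np.array(obs_vals),
                                               observable_name=name)
            dome = hydration.dome_test(series)
            report.series[name] = {
                "is_dome": dome.is_dome, "peak_location": dome.peak_location,
                "monotone_sse": dome.monotone_sse, "unimodal_sse": dome.unimodal_sse,
                "improvement": dome.improvement, "n_points": len(series),
            }
        except DesfoldError as e:
            report.series[name] = {"error": str(e)}

    report.provenance = {
        "package_version": __version__,
        "seed": seed,
        "tref_celsius": float(config.get("tref_celsius", DEFAULT_TREF_CELSIUS)),
        "input_digests": digests,
        "config": config,
    }
    return report


def make_plots(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Hydration-series plots (observable vs wt % water), one file each."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, dome in report.series.items():
        if "error" in dome:
            continue
        stage, key = SERIES_OBSERVABLES[name]
        pts = [(e["wt_percent"],
                e[stage]["fractions"]["alpha"] if key is None else e[stage].get(key))
               for e in report.samples.values() if stage in e]
        pts = sorted((w, v) for w, v in pts if v is not None)
        if not pts:
            continue
        w, v = zip(*pts)
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.plot(w, v, "o-", ms=5)
        if dome.get("is_dome"):
            ax.axvline(dome["peak_location"], ls="--", color="crimson", lw=1,
                       label=f"dome peak {dome['peak_location']:.1f} wt %")
            ax.legend(frameon=False, fontsize=8)
        ax.set_xlabel("water content (wt %)")
        ax.set_ylabel(name)
        fig.tight_layout()
        path = outdir / f"series_{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
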