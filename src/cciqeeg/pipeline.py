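"""End-to-end orchestration: cohort synthesis through risk-score fitting.

Stages communicate through files inside the run directory so each one is
independently re-runnable; every stage writes a ``*_meta.json`` embedding
the configuration hash, and downstream stages refuse inputs whose hash
does not match their own configuration.

The qualitative-pattern table evaluates ten directional strain findings
(baseline slow-wave excess in the kindling-resistant strain, post-injury
broadband power loss, interhemispheric coherence ordering, entropy and
kurtosis changes) on the synthetic cohort using the stats module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import io as cio
from . import riskscore as rs
from . import stats as cstats
from . import synth
from .config import BIN_FREQS
from .preprocess import EPOCH_LABELS, extract_epochs

SUSCEPTIBLE_STRAIN = "PPKS"


@dataclass(frozen=True)
class RunConfig:
    """One reproducible analysis run; all defaults mirror the study scheme."""

    seed: int = 1
    n_per_strain: int = 10
    alpha: float = 0.05
    #: construct-level p above which a "no change" finding is accepted
    no_change_alpha: float = 0.01
    l0_penalty: float = rs.DEFAULT_L0
    max_terms: int = rs.DEFAULT_MAX_TERMS
    out_dir: str = "cciqeeg_run"

    def hashable_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # output location must not alter results
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.hashable_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _log(stage: str, t0: float) -> None:
    print(f"[cciqeeg] {stage}: {time.time() - t0:.1f}s", file=sys.stderr)


def _write_meta(path: Path, config: RunConfig, stage: str) -> None:
    meta = {"stage": stage, "config_hash": config.config_hash(),
            "config": config.hashable_dict()}
    path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def _check_meta(path: Path, config: RunConfig) -> None:
    if not path.exists():
        raise FileNotFoundError(f"missing stage metadata {path}")
    meta = json.loads(path.read_text())
    if meta["config_hash"] != config.config_hash():
        raise ValueError(
            f"config hash mismatch: {path} was produced under "
            f"{meta['config_hash']}, current config is {config.config_hash()}"
        )


def synth_stage(config: RunConfig, out: Path) -> None:
    """Generate the cohort; write per-subject recordings and the manifest."""
    t0 = time.time()
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    specs = synth.cohort_specs(config.n_per_strain, config.seed)
    for spec in specs:
        rec = synth.generate_recording(spec)
        cio.write_recording_npy(rec, rec_dir / f"{spec.subject_id}.npy")
    synth.cohort_manifest(specs).to_csv(out / "manifest.csv", index=False)
    _write_meta(out / "synth_meta.json", config, "synth")
    _log("synth", t0)


def compute_subject_tables(
    rec, subject: str, strain: str, labels: tuple[str, ...] = EPOCH_LABELS
) -> tuple[list[dict], list[dict], list[dict]]:
    """Feature, normalized-spectrum, and coherence rows for one recording.

    Spectra are normalized to the subject's baseline total power (mean of
    the two sides' PSD integrals over the baseline epoch).
    """
    epochs = extract_epochs(rec)
    base_spectra = feat.epoch_spectra(epochs["baseline"], rec.ipsilateral_channel)
    baseline_total = float(
        np.mean([feat.total_power(s) for s in base_spectra.values()])
    )
    feat_rows, spec_rows, coh_rows = [], [], []
    for label in labels:
        ep = epochs[label]
        fv = feat.build_features(ep, rec.ipsilateral_channel)
        feat_rows.append({"subject": subject, "strain": strain, "epoch": label, **fv})
        for side, spectrum in feat.epoch_spectra(ep, rec.ipsilateral_channel).items():
            norm = feat.normalize_to_baseline(spectrum, baseline_total)
            for f0, p0 in zip(BIN_FREQS, norm.power):
                spec_rows.append(
                    {"subject": subject, "strain": strain, "epoch": label,
                     "side": side, "freq": float(f0), "power": float(p0)}
                )
        cs = feat.coherence(ep.left, ep.right, ep.fs)
        for f0, c0 in zip(BIN_FREQS, cs.cxy):
            coh_rows.append(
                {"subject": subject, "strain": strain, "epoch": label,
                 "freq": float(f0), "cxy": float(c0)}
            )
    return feat_rows, spec_rows, coh_rows


def cohort_tables(
    n_per_strain: int, seed: int, labels: tuple[str, ...] = EPOCH_LABELS
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """In-memory features/spectra/coherence tables for a synthetic cohort."""
    frows, srows, crows = [], [], []
    for spec in synth.cohort_specs(n_per_strain, seed):
        rec = synth.generate_recording(spec)
        f, s, c = compute_subject_tables(rec, spec.subject_id, spec.strain, labels)
        frows += f
        srows += s
        crows += c
    return pd.DataFrame(frows), pd.DataFrame(srows), pd.DataFrame(crows)


def features_stage(config: RunConfig, out: Path) -> None:
    """Epoch, filter, and reduce every recording to features and spectra."""
    t0 = time.time()
    _check_meta(out / "synth_meta.json", config)
    manifest = pd.read_csv(out / "manifest.csv")
    feat_rows, spec_rows, coh_rows = [], [], []
    sex_by_subject = dict(zip(manifest["subject_id"], manifest["sex"]))
    for row in manifest.itertuples():
        rec = cio.read_recording_npy(out / "recordings" / f"{row.subject_id}.npy")
        f, s, c = compute_subject_tables(rec, row.subject_id, row.strain)
        feat_rows += f
        spec_rows += s
        coh_rows += c
    features_df = pd.DataFrame(feat_rows)
    features_df.insert(2, "sex", features_df["subject"].map(sex_by_subject))
    features_df.to_csv(out / "features.csv", index=False)
    pd.DataFrame(spec_rows).to_csv(out / "spectra.csv", index=False)
    pd.DataFrame(coh_rows).to_csv(out / "coherence.csv", index=False)
    _write_meta(out / "features_meta.json", config, "features")
    _log("features", t0)


def _two_epoch_test(per_subject: pd.DataFrame, value: str, alpha: float):
    """Baseline vs immediate-post comparison of one scalar; returns
    (p, post_mean - baseline_mean)."""
    res = cstats.anova_tukey(per_subject[value], per_subject["epoch"])
    cmp = res.pair("baseline", "post_0.5")
    sign = 1.0 if cmp.group2 == "post_0.5" else -1.0
    return res.p, sign * cmp.diff


def evaluate_strain_patterns(
    features: pd.DataFrame,
    spectra: pd.DataFrame,
    coherence: pd.DataFrame,
    alpha: float = 0.05,
    no_change_alpha: float = 0.01,
) -> dict[str, bool]:
    """Ten directional strain findings, each judged on the cohort tables.

    Positive findings require construct-level significance at *alpha* with
    the correct direction of group means; "no change" findings require the
    construct-level p to stay above *no_change_alpha*.
    """
    out: dict[str, bool] = {}
    side_mean = (
        spectra.groupby(["subject", "strain", "epoch", "freq"], observed=True)["power"]
        .mean().reset_index()
    )
    base = side_mean[side_mean["epoch"] == "baseline"]

    res = cstats.binwise_model(base, "strain", alpha=alpha)
    delta_by_strain = base[base["freq"] <= 2.0].groupby("strain", observed=True)["power"].mean()
    low_hit = any(lo <= 2.0 for lo, hi in res.intervals["strain"])
    out["baseline_strain_effect_low_freq"] = bool(
        res.effects["strain"].p < alpha
        and low_hit
        and delta_by_strain.idxmax() == "PPKR"
    )
    fast = base[base["freq"] >= 4.0].groupby("strain", observed=True)["power"].mean()
    out["baseline_ppkr_fast_deficit"] = bool(
        fast["PPKR"] < fast["PPKS"] and fast["PPKR"] < fast["SD"]
    )

    pair = side_mean[side_mean["epoch"].isin(["baseline", "post_0.5"])]
    for strain in synth.STRAINS:
        sub = pair[pair["strain"] == strain]
        res = cstats.binwise_model(sub, "epoch", alpha=alpha)
        eff = res.effects["epoch"]
        totals = sub.groupby(["epoch", "subject"], observed=True)["power"].sum()
        drop = totals.loc["post_0.5"].mean() < totals.loc["baseline"].mean()
        if strain == "PPKS":
            out["post_power_stable_ppks"] = bool(eff.p > no_change_alpha)
        else:
            out[f"post_power_loss_{strain.lower()}"] = bool(eff.p < alpha and drop)

    coh_pair = coherence[coherence["epoch"].isin(["baseline", "post_0.5"])]
    mid_ok = True
    for strain in synth.STRAINS:
        sub = coh_pair[coh_pair["strain"] == strain]
        # per subject & epoch mean over 3-7 Hz
        per = (
            sub[(sub["freq"] >= 3.0) & (sub["freq"] <= 7.0)]
            .groupby(["subject", "epoch"], observed=True)["cxy"].mean().reset_index()
        )
        p, delta = _two_epoch_test(per, "cxy", alpha)
        mid_ok &= bool(p < alpha and delta < 0)
    out["post_coherence_drop_3_7hz_all_strains"] = bool(mid_ok)

    post_delta = (
        coherence[(coherence["epoch"] == "post_0.5") & (coherence["freq"] <= 4.0)]
        .groupby(["subject", "strain"], observed=True)["cxy"].mean().reset_index()
    )
    res = cstats.anova_tukey(post_delta["cxy"], post_delta["strain"])
    means = res.group_means
    ordered = means["PPKS"] < means["SD"] < means["PPKR"]
    pairwise = all(
        res.pair(a, b).p_adj < alpha
        for a, b in (("PPKS", "SD"), ("SD", "PPKR"), ("PPKS", "PPKR"))
    )
    out["post_delta_coherence_ordering"] = bool(ordered and pairwise)

    # Entropy and kurtosis findings are judged on per-subject injury
    # change scores (post minus baseline), which cancel stable
    # between-animal spectral differences; strains are then compared with
    # Tukey HSD, and "no change" findings additionally require the
    # unpaired baseline-vs-post test to stay quiet.
    fpair = features[features["epoch"].isin(["baseline", "post_0.5"])]

    def changes(column: str) -> pd.DataFrame:
        piv = fpair.pivot_table(
            index=["subject", "strain"], columns="epoch", values=column
        ).reset_index()
        piv["change"] = piv["post_0.5"] - piv["baseline"]
        return piv

    ent = changes("entropy_ipsi")
    res = cstats.anova_tukey(ent["change"], ent["strain"])
    m = res.group_means
    out["entropy_drop_ipsi_ppks_sd"] = bool(
        res.p < alpha
        and m["PPKS"] < 0 and m["SD"] < 0
        and res.pair("PPKS", "PPKR").p_adj < alpha
        and res.pair("SD", "PPKR").p_adj < alpha
    )
    ppkr_ent = fpair[fpair["strain"] == "PPKR"]
    p_ent, _ = _two_epoch_test(ppkr_ent, "entropy_ipsi", alpha)
    out["entropy_stable_ppkr"] = bool(p_ent > no_change_alpha)

    kur = changes("kurtosis_ipsi")
    res = cstats.anova_tukey(kur["change"], kur["strain"])
    m = res.group_means
    out["kurtosis_rise_ppkr"] = bool(
        m["PPKR"] > 0
        and res.pair("PPKR", "PPKS").p_adj < alpha
        and res.pair("PPKR", "SD").p_adj < alpha
    )
    kurt_null_ok = bool(res.pair("PPKS", "SD").p_adj > no_change_alpha)
    for strain in ("PPKS", "SD"):
        p_kur, _ = _two_epoch_test(fpair[fpair["strain"] == strain], "kurtosis_ipsi", alpha)
        kurt_null_ok &= bool(p_kur > no_change_alpha)
    out["kurtosis_stable_ppks_sd"] = kurt_null_ok
    return out


def stats_stage(config: RunConfig, out: Path) -> dict:
    """Binwise construct effects plus the qualitative-pattern table."""
    t0 = time.time()
    _check_meta(out / "features_meta.json", config)
    features = pd.read_csv(out / "features.csv")
    spectra = pd.read_csv(out / "spectra.csv")
    coherence = pd.read_csv(out / "coherence.csv")

    side_mean = (
        spectra.groupby(["subject", "strain", "epoch", "freq"], observed=True)["power"]
        .mean().reset_index()
    )
    base = side_mean[side_mean["epoch"] == "baseline"]
    baseline_strain = cstats.binwise_model(base, "strain", alpha=config.alpha)
    effects = {
        "baseline_power_strain": {
            "F": baseline_strain.effects["strain"].F,
            "p": baseline_strain.effects["strain"].p,
            "logworth": baseline_strain.effects["strain"].logworth,
            "significant_intervals_hz": baseline_strain.intervals["strain"],
        }
    }
    pair = side_mean[side_mean["epoch"].isin(["baseline", "post_0.5"])]
    for strain in synth.STRAINS:
        res = cstats.binwise_model(
            pair[pair["strain"] == strain], "epoch", alpha=config.alpha
        )
        eff = res.effects["epoch"]
        effects[f"power_timepoint_{strain}"] = {
            "F": eff.F, "p": eff.p, "logworth": eff.logworth,
            "significant_intervals_hz": res.intervals["epoch"],
        }
    patterns = evaluate_strain_patterns(
        features, spectra, coherence,
        alpha=config.alpha, no_change_alpha=config.no_change_alpha,
    )
    result = {
        "effects": effects,
        "qualitative_patterns": patterns,
        "n_patterns_reproduced": int(sum(patterns.values())),
        "config_hash": config.config_hash(),
    }
    (out / "stats.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    _write_meta(out / "stats_meta.json", config, "stats")
    _log("stats", t0)
    return result


def riskscore_stage(config: RunConfig, out: Path) -> rs.RiskModel:
    """Fit the integer scorecard on immediate post-injury features."""
    t0 = time.time()
    _check_meta(out / "features_meta.json", config)
    features = pd.read_csv(out / "features.csv")
    post = features[features["epoch"] == "post_0.5"].reset_index(drop=True)
    X = post[list(feat.FEATURE_NAMES)]
    y = (post["strain"] == SUSCEPTIBLE_STRAIN).to_numpy()
    model = rs.fit_riskslim(
        X, y, max_terms=config.max_terms, l0_penalty=config.l0_penalty
    )
    payload = model.to_dict()
    payload["config_hash"] = config.config_hash()
    (out / "riskmodel.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    (out / "scorecard.md").write_text(model.scorecard_markdown() + "\n")
    _write_meta(out / "riskscore_meta.json", config, "riskscore")
    _log("riskscore", t0)
    return model


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the report bundle summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_stage(config, out)
    features_stage(config, out)
    stats_result = stats_stage(config, out)
    model = riskscore_stage(config, out)
    report = {
        "config": config.hashable_dict(),
        "config_hash": config.config_hash(),
        "qualitative_patterns": stats_result["qualitative_patterns"],
        "n_patterns_reproduced": stats_result["n_patterns_reproduced"],
        "risk_model": {
            "terms": [t.rule.describe() for t in model.terms],
            "intercept": model.intercept,
            "objective": model.objective,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
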