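"""End-to-end orchestration: profiles -> zonation -> speciation -> kinetics
-> omics -> statistics -> report bundle.

All concentrations are normalized at ingest (fM/pM/uM -> mol/L internally);
O2 stays in mL/L because the zone definitions are expressed in that unit.
Every run writes a manifest (config hash, seed, versions) so outputs are
traceable; deterministic stages are bit-identical under rerun.

Synthetic profiles emulate blank-corrected (reported) concentrations, so the
blank-correction stage is off by default; enable ``apply_blank_correction``
when feeding raw field determinations.
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

from . import __version__
from .kinetics import (
    BlankModel, DEFAULT_BLANKS, IncubationSeries, TYPICAL_DL_K_METH,
    blank_correct_hgt, blank_correct_mehg, estimate_k_demeth, estimate_k_meth,
)
from .omics import EXPRESSION_THRESHOLD, normalize_to_gyrb
from .speciation import SpeciationTableau, default_tableau, load_tableau, speciate_profile
from .stats import joint_model_report
from .synth import H2S_DETECT_LIMIT, classify_zone

__all__ = ["RunConfig", "fit_rates", "abundance_table", "build_joined", "run_all"]

log = logging.getLogger("hgstrat")


@dataclass
class RunConfig:
    """Paths, constants and thresholds of one pipeline run."""

    profile_csv: str
    incubations_csv: str
    coverage_csv: str
    outdir: str
    tableau_path: str | None = None      # None -> shipped default tableau
    blanks: BlankModel = field(default_factory=BlankModel)
    p_cutoff: float = 0.05
    expression_threshold: float = EXPRESSION_THRESHOLD
    o2_normoxic_cutoff: float = 2.0
    o2_euxinic_cutoff: float = 0.1
    h2s_detect_limit: float = H2S_DETECT_LIMIT
    apply_blank_correction: bool = False
    use_speciation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cutoff", "expression_threshold", "o2_normoxic_cutoff",
                     "o2_euxinic_cutoff", "h2s_detect_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        """Load a run config from a YAML file; ``blanks`` may be a mapping."""
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if isinstance(doc.get("blanks"), dict):
            doc["blanks"] = BlankModel(**doc["blanks"])
        return cls(**doc)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _series_from_frame(df: pd.DataFrame) -> list[IncubationSeries]:
    out = []
    for (sid, depth), grp in df.groupby(["sample_id", "depth_m"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(IncubationSeries(
            sample_id=str(sid), depth=float(depth),
            times=tuple(grp["time_h"]),
            me199=tuple(grp["me199_fM"]),
            me201=tuple(grp["me201_fM"]),
            spike199=float(grp["spike199_pM"].iloc[0]),
            spike201=float(grp["spike201_pM"].iloc[0]),
        ))
    return out


def fit_rates(incubations: pd.DataFrame | list[IncubationSeries],
              p_cutoff: float = 0.05) -> pd.DataFrame:
    """Fit k_meth and k_demeth for every incubation series."""
    series = (incubations if isinstance(incubations, list)
              else _series_from_frame(incubations))
    rows = []
    for s in series:
        km = estimate_k_meth(s)
        try:
            kd = estimate_k_demeth(s)
            kd_vals = dict(k_demeth=kd.k, k_demeth_p=kd.p_value,
                           k_demeth_detectable=kd.p_value < p_cutoff and kd.k > 0)
        except ValueError as exc:
            kd_vals = dict(k_demeth=np.nan, k_demeth_p=np.nan,
                           k_demeth_detectable=False)
            log.warning("demethylation fit failed for %s: %s", s.sample_id, exc)
        rows.append({
            "sample_id": s.sample_id, "depth_m": s.depth,
            "k_meth": km.k, "k_meth_se": km.std_err, "k_meth_p": km.p_value,
            "k_meth_detectable": km.p_value < p_cutoff and km.k > 0,
            "n_points": km.n_points, **kd_vals,
        })
    return pd.DataFrame(rows)


def abundance_table(coverage: pd.DataFrame) -> pd.DataFrame:
    """Wide per-sample gyrB-normalized hgcA/hgcB gene/transcript abundances.

    Rows of the same family/molecule within a sample (per-MAG + unbinned)
    are summed after normalization.
    """
    norm = normalize_to_gyrb(coverage)
    hgc = norm[norm["gene_family"].isin(["hgcA", "hgcB"])]
    agg = (hgc.groupby(["sample_id", "molecule", "gene_family"])["value"]
           .sum(min_count=1).reset_index())
    agg["column"] = (agg["gene_family"].str.lower().str.replace("hgc", "hgc")
                     .map({"hgca": "hgca", "hgcb": "hgcb"})
                     + "_" + agg["molecule"])
    wide = agg.pivot(index="sample_id", columns="column", values="value").reset_index()
    wide.columns.name = None
    return wide


def build_joined(profile: pd.DataFrame, speciation: pd.DataFrame | None,
                 rates: pd.DataFrame, abundances: pd.DataFrame,
                 h2s_detect_limit: float = H2S_DETECT_LIMIT) -> pd.DataFrame:
    """Join per-depth chemistry, speciation, rates and molecular abundances.

    Restricted to samples with molecular data; non-detect k_meth becomes NaN
    (flagged by ``k_meth_detectable``), left to the statistics layer's
    documented substitution rule.
    """
    df = profile.copy()
    df["zone"] = [classify_zone(o, h, h2s_detect_limit)
                  for o, h in zip(df["o2_mLL"], df["h2s_uM"])]
    df["mehg_hgt_ratio"] = df["mehg_fM"] / df["hgt_fM"]
    keep = ["sample_id", "depth_m", "zone", "hgt_fM", "mehg_fM", "mehg_hgt_ratio"]
    df = df[keep]
    if speciation is not None:
        df = df.merge(
            speciation[["depth_m", "diss_sulfide_fraction", "diss_sulfide_conc_M"]],
            on="depth_m", how="left",
        ).rename(columns={"diss_sulfide_conc_M": "diss_sulfide_conc"})
    rates = rates.copy()
    rates["k_meth"] = rates["k_meth"].where(rates["k_meth_detectable"])
    df = df.merge(rates[["sample_id", "k_meth", "k_meth_detectable"]],
                  on="sample_id", how="left")
    df = df.merge(abundances, on="sample_id", how="inner")
    df = df.rename(columns={"mehg_fM": "mehg"})
    return df


def run_all(config: RunConfig) -> dict:
    """Run every stage, write the report bundle, return paths + the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    status = "complete"

    profile = pd.read_csv(config.profile_csv)
    incub = pd.read_csv(config.incubations_csv)
    coverage = pd.read_csv(config.coverage_csv)

    if config.apply_blank_correction:
        profile["hgt_fM"] = [
            blank_correct_hgt(v * 1e-3, config.blanks) * 1e3 for v in profile["hgt_fM"]
        ]
        profile["mehg_fM"] = [
            blank_correct_mehg(v, config.blanks) for v in profile["mehg_fM"]
        ]

    spec_table = None
    if config.use_speciation:
        tableau = (load_tableau(config.tableau_path) if config.tableau_path
                   else default_tableau())
        log.info("speciating %d depths (tableau %s)", len(profile), tableau.version)
        spec_table = speciate_profile(tableau, profile)
        spec_table.to_csv(outdir / "speciation.csv", index=False)
        written["speciation"] = str(outdir / "speciation.csv")

    rates = fit_rates(incub, p_cutoff=config.p_cutoff)
    rates.to_csv(outdir / "rates.csv", index=False)
    written["rates"] = str(outdir / "rates.csv")

    abund = abundance_table(coverage)
    abund.to_csv(outdir / "abundance.csv", index=False)
    written["abundance"] = str(outdir / "abundance.csv")

    joined = build_joined(profile, spec_table, rates, abund,
                          h2s_detect_limit=config.h2s_detect_limit)
    joined.to_csv(outdir / "joined.csv", index=False)
    written["joined"] = str(outdir / "joined.csv")

    try:
        report = joint_model_report(
            joined,
            nondetect_substitute=TYPICAL_DL_K_METH / 2,
            use_speciation=config.use_speciation,
        )
    except ValueError as exc:
        report = {"error": str(exc)}
        status = "partial: statistics failed"
        log.error("statistics stage failed: %s", exc)
    with open(outdir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    written["stats_report"] = str(outdir / "stats_report.json")

    manifest = {
        "package": "hgstrat",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "status": status,
        "tableau": config.tableau_path or "shipped:baltic-v1",
        "speciation_used": config.use_speciation,
        "outputs": written,
        "n_profile_rows": int(len(profile)),
        "n_incubation_series": int(rates.shape[0]),
        "n_joined_samples": int(len(joined)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    written["manifest"] = str(outdir / "manifest.json")
    return {"manifest": manifest, "report": report, "written": written}
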