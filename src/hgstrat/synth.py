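"""Synthetic redox-stratified water-column datasets.

Generates the three tables the pipeline consumes — a depth profile of
ancillary and Hg chemistry, tracer-incubation time series per depth, and a
gene/transcript coverage table — with the biogeochemical structure of a
stratified brackish basin: an oxygenated surface layer, a redox transition
zone where O2 falls from 2 to 0.1 mL/L, and a euxinic zone with sulfide
accumulating toward the bottom.  Hg concentrations, MeHg/HgT ratios, rate
constants and hgc-gene abundance scale with the redox zone; measurement
noise is multiplicative at a configurable relative SD (default 4 %, the
field-replicate figure for MeHg determinations).

Every draw is governed by the mandatory config seed; identical configs
produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import IncubationSeries

__all__ = [
    "StationConfig",
    "WaterColumnDataset",
    "classify_zone",
    "interpolate_ancillary",
    "generate_dataset",
    "by32_config",
    "by15_config",
]

#: default "detectable H2S" threshold, umol/L
H2S_DETECT_LIMIT = 0.1
#: O2 cutoffs (mL/L) between normoxic/transition and transition/euxinic water
O2_NORMOXIC_CUTOFF = 2.0
O2_EUXINIC_CUTOFF = 0.1

_HGC_TAXA = (
    "Desulfobacterota", "PVC superphylum", "Chloroflexota", "AABM5-125-24",
)
#: euxinic-zone share of hgcA / hgcB transcript abundance carried by hgc+ MAGs
_MAG_TRANSCRIPT_SHARE = {"hgcA": 0.44, "hgcB": 0.59}


def classify_zone(o2: float, h2s: float, h2s_detect_limit: float = H2S_DETECT_LIMIT) -> str:
    """Three-way redox zonation from O2 (mL/L) and H2S (umol/L).

    normoxic: O2 > 2 mL/L; transition: 0.1 <= O2 <= 2 mL/L; euxinic:
    O2 < 0.1 mL/L with detectable H2S.  Anoxic-but-sulfide-free water
    (O2 < 0.1, H2S at or below the detection threshold) is classed as
    transition — the zonation has no separate label for it.
    """
    if o2 < 0 or h2s < 0:
        raise ValueError("O2 and H2S must be >= 0")
    if o2 > O2_NORMOXIC_CUTOFF:
        return "normoxic"
    if o2 < O2_EUXINIC_CUTOFF and h2s > h2s_detect_limit:
        return "euxinic"
    return "transition"


def interpolate_ancillary(depths_measured, values, depths_target):
    """Linear interpolation from the two nearest (bracketing) depths.

    Targets outside the measured depth range raise rather than extrapolate.
    """
    zm = np.asarray(depths_measured, float)
    v = np.asarray(values, float)
    zt = np.atleast_1d(np.asarray(depths_target, float))
    if zm.size < 2:
        raise ValueError("need >= 2 measured depths")
    if np.any(np.diff(zm) <= 0):
        raise ValueError("measured depths must be strictly increasing")
    if np.any(zt < zm[0]) or np.any(zt > zm[-1]):
        raise ValueError("target depth outside measured range (no extrapolation)")
    out = np.interp(zt, zm, v)
    return out if np.ndim(depths_target) else float(out[0])


@dataclass(frozen=True)
class StationConfig:
    """Generating parameters of one station's synthetic water column."""

    name: str
    depth_grid: tuple[float, ...]
    chemocline_depth: float          # m, O2 sigmoid midpoint
    chemocline_width: float          # m, O2 sigmoid scale
    h2s_onset_depth: float           # m, sulfide appears below this
    bottom_depth: float              # m, water-sediment interface
    o2_surface: float = 6.0          # mL/L
    h2s_max: float = 35.0            # umol/L at the bottom
    doc: float = 4.0                 # mg C/L
    #: per-zone gyrB-normalized hgcA abundance scale (genes); transcripts
    #: are scaled by hgca_transcript_factor on top
    hgca_scale: dict = field(default_factory=lambda: {
        "normoxic": 0.004, "transition": 0.12, "euxinic": 0.5})
    hgca_transcript_factor: float = 1.2
    #: per-depth true rate constants; None -> zone-based defaults
    k_meth_true: tuple[float, ...] | None = None
    k_demeth_true: tuple[float, ...] | None = None
    noise_rsd: float = 0.04
    incubation_times: tuple[float, ...] = (0.0, 4.0, 8.0, 24.0)
    spike199: float = 260.0          # pM
    spike201: float = 2.0            # pM
    n_molecular_samples: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.depth_grid, float)
        if z.size < 3 or np.any(np.diff(z) <= 0):
            raise ValueError("depth grid must be increasing with >= 3 depths")
        if min(self.o2_surface, self.h2s_max, self.doc) <= 0:
            raise ValueError("ranges must be positive")
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be >= 0")
        for k in ("k_meth_true", "k_demeth_true"):
            v = getattr(self, k)
            if v is not None and len(v) != z.size:
                raise ValueError(f"{k} must match the depth grid")


def by32_config(seed: int = 0, **overrides) -> StationConfig:
    """Sharp-redoxcline preset (Landsort-Deep-like): chemocline ~70-80 m."""
    defaults = dict(
        name="BY32",
        depth_grid=(5, 30, 60, 70, 75, 78, 80, 90, 120, 160, 190),
        chemocline_depth=72.0,
        chemocline_width=1.8,
        h2s_onset_depth=78.0,
        bottom_depth=204.0,
        h2s_max=35.0,
        incubation_times=(0.0, 4.0, 8.0, 24.0),
        # study conditions: methylation undetectable in normoxic water, near
        # the detection limit low in the transition zone, rising to
        # 1.47e-3 /h at the deepest euxinic depth; demethylation detectable
        # only at the bottom (7.6e-3 /h)
        k_meth_true=(0, 0, 0, 0, 0.016e-3, 0.02e-3, 0.25e-3,
                     0.63e-3, 0.9e-3, 1.2e-3, 1.47e-3),
        k_demeth_true=(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 7.6e-3),
        seed=seed,
    )
    defaults.update(overrides)
    return StationConfig(**defaults)


def by15_config(seed: int = 0, **overrides) -> StationConfig:
    """Extended-redoxcline preset (Gotland-Deep-like): transition ~80-150 m."""
    defaults = dict(
        name="BY15",
        depth_grid=(5, 30, 60, 80, 100, 120, 140, 150, 160, 180, 200, 230),
        chemocline_depth=60.0,
        chemocline_width=22.0,
        h2s_onset_depth=148.0,
        bottom_depth=240.0,
        h2s_max=100.0,
        incubation_times=(0.0, 4.0, 12.0, 24.0),
        # study conditions: k_meth below the detection limit throughout the
        # column except the deepest euxinic depth (1.20e-3 /h at 230 m),
        # where demethylation (5.1e-3 /h) is also detectable
        k_meth_true=(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1.20e-3),
        k_demeth_true=(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 5.1e-3),
        seed=seed,
    )
    defaults.update(overrides)
    return StationConfig(**defaults)


@dataclass
class WaterColumnDataset:
    """One generated station: profile, incubations, coverage and the truth."""

    profile: pd.DataFrame
    incubations: list[IncubationSeries]
    coverage: pd.DataFrame
    t0_me199_replicates: tuple[float, ...]
    truth: dict

    def incubation_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.incubations:
            for t, a, b in zip(s.times, s.me199, s.me201):
                rows.append({
                    "sample_id": s.sample_id, "depth_m": s.depth, "time_h": t,
                    "me199_fM": a, "me201_fM": b,
                    "spike199_pM": s.spike199, "spike201_pM": s.spike201,
                })
        return pd.DataFrame(rows)


def _o2_profile(cfg: StationConfig, z: np.ndarray) -> np.ndarray:
    return cfg.o2_surface / (1.0 + np.exp((z - cfg.chemocline_depth) / cfg.chemocline_width))

def _h2s_profile(cfg: StationConfig, z: np.ndarray) -> np.ndarray:
    frac = np.clip((z - cfg.h2s_onset_depth) / (cfg.bottom_depth - cfg.h2s_onset_depth), 0, 1)
    return cfg.h2s_max * np.sqrt(frac)


def _default_k_meth(zones, z, cfg) -> np.ndarray:
    out = np.zeros(len(z))
    eux = [i for i, zn in enumerate(zones) if zn == "euxinic"]
    for i, zn in enumerate(zones):
        if zn == "transition":
            out[i] = 0.02e-3
        elif zn == "euxinic":
            z0 = z[eux[0]]
            span = max(cfg.bottom_depth - z0, 1.0)
            out[i] = 0.25e-3 + (1.5e-3 - 0.25e-3) * (z[i] - z0) / span
    return out


def _default_k_demeth(zones, z, cfg) -> np.ndarray:
    # demethylation detectable only near the bottom of the euxinic zone
    out = np.zeros(len(z))
    for i, zn in enumerate(zones):
        if zn == "euxinic" and z[i] >= cfg.bottom_depth - 0.15 * cfg.bottom_depth:
            out[i] = 6.0e-3
    return out


def generate_dataset(cfg: StationConfig) -> WaterColumnDataset:
    """Generate one station's dataset; pure function of the config."""
    # fold the station name into the entropy so two stations sharing a seed
    # still draw independent noise
    ss = np.random.SeedSequence([cfg.seed, *cfg.name.encode()])
    key_profile, key_cov, key_incub, key_t0 = ss.spawn(4)
    rng = np.random.default_rng(key_profile)

    z = np.asarray(cfg.depth_grid, float)
    o2 = _o2_profile(cfg, z)
    h2s = _h2s_profile(cfg, z)
    zones = [classify_zone(a, b) for a, b in zip(o2, h2s)]

    # ancillary climate: warm fresh surface, cold saline deep water
    temp = 4.0 + 12.0 / (1.0 + np.exp((z - 25.0) / 8.0))
    sal = 7.0 + 4.0 / (1.0 + np.exp(-(z - 65.0) / 15.0))
    doc = np.maximum(cfg.doc + rng.normal(0, 0.05 * cfg.doc, z.size), 0.5)

    hgt = np.empty(z.size)
    mehg = np.empty(z.size)
    for i, zn in enumerate(zones):
        if zn == "normoxic":
            mehg[i] = rng.uniform(20.0, 48.0)
            hgt[i] = rng.uniform(300.0, 640.0)
        elif zn == "transition":
            hgt[i] = rng.uniform(640.0, 1800.0)
            mehg[i] = rng.uniform(0.21, 0.60) * hgt[i]
        else:
            mehg[i] = rng.uniform(1000.0, 1300.0)
            mehg_ratio = rng.uniform(0.50, 0.70)
            hgt[i] = mehg[i] / mehg_ratio

    k_meth = (np.asarray(cfg.k_meth_true, float) if cfg.k_meth_true is not None
              else _default_k_meth(zones, z, cfg))
    k_demeth = (np.asarray(cfg.k_demeth_true, float) if cfg.k_demeth_true is not None
                else _default_k_demeth(zones, z, cfg))

    profile = pd.DataFrame({
        "sample_id": [f"{cfg.name}-{int(d)}m" for d in z],
        "depth_m": z, "temp_C": temp, "salinity_psu": sal,
        "o2_mLL": o2, "h2s_uM": h2s, "doc_mgL": doc,
        "hgt_fM": hgt, "mehg_fM": mehg,
        "mehg_hgt_ratio": mehg / hgt,
        "zone": zones,
        "k_meth_true": k_meth, "k_demeth_true": k_demeth,
    })

    # --- incubations ------------------------------------------------------
    # Me199Hg: tracer-formed MeHg grows linearly, k * spike * t, with a t=0
    # noise floor whose SD is ~33 fM at the default 4 % RSD (it scales with
    # noise_rsd so noise-free configs are exactly linear).
    floor_sd = 833.25 * cfg.noise_rsd
    baseline = 3.0 * floor_sd
    times = np.asarray(cfg.incubation_times, float)
    incubations = []
    for i, child in enumerate(key_incub.spawn(z.size)):
        r = np.random.default_rng(child)
        eps199 = r.normal(0, cfg.noise_rsd, times.size)
        eta = r.normal(0, floor_sd, times.size) if floor_sd > 0 else np.zeros(times.size)
        me199 = baseline + k_meth[i] * cfg.spike199 * 1e3 * times * (1 + eps199) + eta
        eps201 = r.normal(0, cfg.noise_rsd, times.size)
        me201 = cfg.spike201 * 1e3 * np.exp(-k_demeth[i] * times) * (1 + eps201)
        incubations.append(IncubationSeries(
            sample_id=f"{cfg.name}-{int(z[i])}m",
            depth=float(z[i]),
            times=tuple(times),
            me199=tuple(np.maximum(me199, 0.0)),
            me201=tuple(np.maximum(me201, 1e-9)),
            spike199=cfg.spike199, spike201=cfg.spike201,
        ))

    rng_t0 = np.random.default_rng(key_t0)
    t0_reps = tuple(baseline + rng_t0.normal(0, floor_sd, 6)) if floor_sd > 0 \
        else (baseline,) * 6

    coverage = _generate_coverage(cfg, profile, np.random.default_rng(key_cov))

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "zones": zones,
        "k_meth_true": k_meth.tolist(),
        "k_demeth_true": k_demeth.tolist(),
        "t0_noise_sd_fM": floor_sd,
        "mag_transcript_share": _MAG_TRANSCRIPT_SHARE,
    }
    return WaterColumnDataset(profile, incubations, coverage, t0_reps, truth)


def _molecular_depths(cfg: StationConfig, profile: pd.DataFrame) -> list[int]:
    """Indices of the molecular sampling depths: 1 normoxic, 2 transition,
    and the rest euxinic (deepest first preference), mirroring the design."""
    idx_by_zone = {zn: profile.index[profile["zone"] == zn].tolist()
                   for zn in ("normoxic", "transition", "euxinic")}
    picks = []
    if idx_by_zone["normoxic"]:
        picks.append(idx_by_zone["normoxic"][-1])
    picks.extend(idx_by_zone["transition"][-2:])
    n_eux = max(cfg.n_molecular_samples - len(picks), 1)
    eux = idx_by_zone["euxinic"]
    if eux:
        step = max(len(eux) // n_eux, 1)
        picks.extend(eux[::-1][::step][:n_eux][::-1])
    return sorted(picks)


def _generate_coverage(cfg: StationConfig, profile: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    mag_ids = [f"bin{i:03d}" for i in (9, 36, 62, 75, 111, 142, 143, 145, 225, 278)]
    for idx in _molecular_depths(cfg, profile):
        sample = profile.loc[idx, "sample_id"]
        zone = profile.loc[idx, "zone"]
        for molecule in ("gene", "transcript"):
            # three gyrB-annotated sequences per sample; mean ~0.04 reads/bp
            gyrb_mean = 0.04 * rng.lognormal(0, 0.2)
            for j in range(3):
                rows.append((sample, molecule, "gyrB", pd.NA, pd.NA,
                             gyrb_mean * rng.lognormal(0, 0.15)))
            scale = cfg.hgca_scale[zone]
            if molecule == "transcript":
                scale = scale * cfg.hgca_transcript_factor
            for fam in ("hgcA", "hgcB"):
                total = scale * gyrb_mean * rng.lognormal(0, 0.3)
                if fam == "hgcB":
                    total *= 0.8
                if zone == "euxinic" and molecule == "transcript":
                    share = _MAG_TRANSCRIPT_SHARE[fam]
                    w = rng.dirichlet(np.ones(len(mag_ids)))
                    for mag, taxon, wi in zip(
                        mag_ids, np.resize(_HGC_TAXA, len(mag_ids)), w
                    ):
                        rows.append((sample, molecule, fam, mag, taxon,
                                     share * total * wi))
                    rows.append((sample, molecule, fam, pd.NA, "unbinned",
                                 (1 - share) * total))
                else:
                    rows.append((sample, molecule, fam, pd.NA, "unbinned", total))
            # metabolic-capacity transcripts for the hgc+ MAGs
            if zone != "normoxic" and molecule == "transcript":
                for mag in mag_ids[:4]:
                    for fam in ("sulfate reduction", "fermentation",
                                "hydrogen oxidation"):
                        rows.append((sample, molecule, fam, mag, "Desulfobacterota",
                                     gyrb_mean * rng.lognormal(-0.5, 0.5)))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "molecule", "gene_family", "mag_id", "taxon", "coverage"],
    )
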