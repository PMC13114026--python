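"""End-to-end pipeline: simulate two-strain cohorts, quantify behavior and
EEG, and write the full table bundle.

The pipeline mirrors a two-cohort design: a behavioral cohort (ascending
tail-clamp MAC staircases and descending righting-reflex staircases, compared
with the gated two-sample rule) and an EEG cohort (per-step BSR and
suppression time, onset concentrations, group-median DSA, theta topographic
maps and anteriorization indices). Every run writes a manifest carrying the
seed, a config hash, and library versions, sufficient to re-run bit-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .montage import default_mouse_montage
from .recording import ConcentrationProtocol
from .spectral import SpectralConfig, group_median_spectrogram, multitaper_spectrogram
from .stats import gated_compare
from .suppression import SuppressionCriteria, bsr_by_step, onset_concentration
from .synthetic import (
    StrainParams,
    b6_like_params,
    btbr_like_params,
    simulate_cohort,
)
from .topography import (
    BandSpec,
    anteriorization_index,
    group_topomap,
    theta_site_power,
)
from .endpoints import StaircaseSpec, cohort_endpoints


@dataclass
class PipelineConfig:
    """All knobs for one reproduction run (defaults are the study conditions)."""

    strains: dict[str, StrainParams] = field(
        default_factory=lambda: {"B6": b6_like_params(), "BTBR": btbr_like_params()}
    )
    # EEG protocol: 2.0 -> 2.8 vol% in 0.2% increments, 5 min per step
    protocol_start: float = 2.0
    protocol_stop: float = 2.8
    protocol_increment: float = 0.2
    step_duration_s: float = 300.0
    fs: float = 500.0
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    criteria: SuppressionCriteria = field(default_factory=SuppressionCriteria)
    band: BandSpec = field(default_factory=BandSpec)
    bsr_channel: str = "F1"
    # group sizes: behavioral (MAC n=10, RR n=8 per strain), EEG BSR cohort
    # (B6 5 / BTBR 8), topography cohort (B6 4 / BTBR 5)
    n_mac: int = 10
    n_rr: int = 8
    n_eeg: dict[str, int] = field(default_factory=lambda: {"B6": 5, "BTBR": 8})
    n_topo: dict[str, int] = field(default_factory=lambda: {"B6": 4, "BTBR": 5})
    jitter_cv: float = 0.02
    topo_bsr_cutoff_percent: float = 5.0
    seed: int = 0
    render_figures: bool = False

    def protocol(self) -> ConcentrationProtocol:
        return ConcentrationProtocol.stepped(
            self.protocol_start,
            self.protocol_stop,
            self.protocol_increment,
            self.step_duration_s,
        )

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj

        return conv(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = dict(raw)
        if "strains" in kwargs:
            kwargs["strains"] = {
                name: StrainParams(**block) for name, block in kwargs["strains"].items()
            }
        for key, typ in (
            ("spectral", SpectralConfig),
            ("criteria", SuppressionCriteria),
            ("band", BandSpec),
        ):
            if key in kwargs:
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)
        return path


def paper_shaped_config(seed: int = 0) -> PipelineConfig:
    """The shipped two-strain configuration (control vs sensitive strain)."""
    return PipelineConfig(seed=seed)


def _topo_params(params: StrainParams, protocol_stop: float) -> StrainParams:
    """Suppression-free variant for the mapping cohort.

    Theta maps describe activity before burst-suppression onset, so the
    topography cohort is generated with the suppression dose-response pushed
    above the protocol range while keeping the strain's theta dynamics.
    """
    return dataclasses.replace(params, bs_ec50=protocol_stop + 1.0)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, seed: Optional[int] = None
) -> dict[str, Path]:
    """Run the full reproduction and write the table bundle into ``outdir``.

    Returns a name -> path map of everything written. Deterministic for a
    fixed (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    protocol = config.protocol()
    montage = default_mouse_montage()
    strains = list(config.strains)
    if len(strains) != 2:
        raise ValidationError("pipeline expects exactly two strain blocks")
    outputs: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        outputs[name] = path

    # -- behavioral cohort -------------------------------------------------
    endpoint_rows, test_rows = [], []
    per_strain_values: dict[tuple[str, str], list[float]] = {}
    for ep, n in (("mac", config.n_mac), ("rr", config.n_rr)):
        spec = StaircaseSpec(endpoint=ep)
        for si, name in enumerate(strains):
            summary = cohort_endpoints(
                [config.strains[name]] * n,
                spec,
                seed=(seed * 7919 + si * 101 + (0 if ep == "mac" else 1)) % 2**31,
            )
            per_strain_values[(ep, name)] = summary.values
            for i, v in enumerate(summary.values):
                endpoint_rows.append(
                    {"endpoint": ep, "strain": name, "subject": i, "value_volpct": v}
                )
        res = gated_compare(
            per_strain_values[(ep, strains[0])], per_strain_values[(ep, strains[1])]
        )
        test_rows.append(
            {
                "endpoint": ep,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    write("endpoints.csv", pd.DataFrame(endpoint_rows))
    write("endpoint_tests.csv", pd.DataFrame(test_rows))

    # -- EEG cohort: BSR / onset / DSA ------------------------------------
    bsr_rows, onset_rows = [], []
    bsr_values: dict[tuple[str, float], list[float]] = {}
    dsa_frames = []
    for si, name in enumerate(strains):
        cohort = simulate_cohort(
            config.strains[name],
            config.n_eeg[name],
            protocol,
            fs=config.fs,
            seed=(seed * 104729 + si) % 2**31,
            jitter_cv=config.jitter_cv,
        )
        specs = []
        for i, (rec, _truth) in enumerate(cohort):
            per_step = bsr_by_step(rec, config.bsr_channel, protocol, config.criteria)
            for row in per_step:
                bsr_rows.append(
                    {
                        "strain": name,
                        "subject": i,
                        "concentration": row.concentration,
                        "bsr_percent": row.bsr_percent,
                        "suppression_time_s": row.suppression_time_s,
                    }
                )
                bsr_values.setdefault((name, row.concentration), []).append(
                    row.bsr_percent
                )
            onset = onset_concentration(per_step)
            onset_rows.append(
                {
                    "strain": name,
                    "subject": i,
                    "onset_volpct": "none" if onset is None else onset,
                }
            )
            specs.append(multitaper_spectrogram(rec, config.bsr_channel, config.spectral))
        med = group_median_spectrogram(specs)
        t_grid, f_grid = np.meshgrid(
            med.window_times_s, med.freqs_hz, indexing="ij"
        )
        dsa_frames.append(
            pd.DataFrame(
                {
                    "strain": name,
                    "time_s": t_grid.ravel(),
                    "freq_hz": f_grid.ravel(),
                    "power": med.power.ravel(),
                }
            )
        )
    write("bsr_by_step.csv", pd.DataFrame(bsr_rows))
    write("onsets.csv", pd.DataFrame(onset_rows))
    write("dsa_group_median.csv", pd.concat(dsa_frames, ignore_index=True))

    mw_rows = []
    for conc in protocol.concentrations:
        a = bsr_values.get((strains[0], conc), [])
        b = bsr_values.get((strains[1], conc), [])
        if len(a) >= 3 and len(b) >= 3:
            res = gated_compare(a, b)
            mw_rows.append(
                {
                    "concentration": conc,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    write("bsr_group_tests.csv", pd.DataFrame(mw_rows))

    # -- topography cohort -------------------------------------------------
    topo_rows, index_rows = [], []
    for si, name in enumerate(strains):
        params = _topo_params(config.strains[name], config.protocol_stop)
        cohort = simulate_cohort(
            params,
            config.n_topo[name],
            protocol,
            fs=config.fs,
            seed=(seed * 15485863 + si) % 2**31,
            jitter_cv=config.jitter_cv,
            jitter_fields=("theta_shift_rate",),
        )
        per_animal = [
            theta_site_power(rec, protocol, config.band, config.spectral, montage)
            for rec, _ in cohort
        ]
        maps = group_topomap(per_animal, montage)
        for conc, topo in sorted(maps.items()):
            for site, p in sorted(topo.site_power.items()):
                topo_rows.append(
                    {"strain": name, "concentration": conc, "site": site, "power": p}
                )
            index_rows.append(
                {
                    "strain": name,
                    "concentration": conc,
                    "anteriorization_index": anteriorization_index(topo),
                    "n_animals": topo.n_animals,
                }
            )
    write("theta_site_power.csv", pd.DataFrame(topo_rows))
    write("anteriorization.csv", pd.DataFrame(index_rows))

    if config.render_figures:
        _render_figures(outdir, outputs)

    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "versions": {
            "sevoeeg": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(outputs),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest.json"] = mpath
    return outputs


def _render_figures(outdir: Path, outputs: dict[str, Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dsa = pd.read_csv(outputs["dsa_group_median.csv"])
    for strain, grp in dsa.groupby("strain"):
        piv = grp.pivot(index="freq_hz", columns="time_s", values="power")
        fig, ax = plt.subplots(figsize=(8, 4))
        db = 10 * np.log10(np.maximum(piv.to_numpy(), np.finfo(float).tiny))
        ax.pcolormesh(piv.columns, piv.index, db, shading="auto", cmap="jet")
        ax.set(
            xlabel="time (s)",
            ylabel="frequency (Hz)",
            ylim=(0, 30),
            title=f"group-median DSA — {strain} (dB)",
        )
        fig.savefig(outdir / f"dsa_{strain}.png", dpi=120)
        plt.close(fig)

    idx = pd.read_csv(outputs["anteriorization.csv"])
    fig, ax = plt.subplots()
    for strain, grp in idx.groupby("strain"):
        ax.plot(grp["concentration"], grp["anteriorization_index"], "o-", label=strain)
    ax.set(xlabel="sevoflurane (vol%)", ylabel="frontal/parietal theta power")
    ax.legend()
    fig.savefig(outdir / "anteriorization.png", dpi=120)
    plt.close(fig)
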