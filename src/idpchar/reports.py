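"""Report assembly: orchestrates full characterization runs.

Two entry points mirror the two halves of a peptide characterization study:
:func:`run_sequence_report` (charge, pI, composition, diagram-of-states,
disorder propensity, hydropathy, membrane partitioning) and
:func:`run_ensemble_report` (chain dimensions with convergence diagnostics,
distance/contact maps, secondary structure, Ramachandran statistics,
clustering, and SAXS-style curve analysis of a generated or supplied
ensemble).  Every output carries the package version, a configuration hash
and the seeds used, so reruns with identical configuration are
bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import conformation as conf
from . import saxs
from .ensembles import (
    BasinMixture,
    DEFAULT_DISORDERED_MIXTURE,
    Ensemble,
    read_ensemble,
    sample_ensemble,
    write_ensemble,
)
from .partitioning import folding_coupled, partition_free_energy
from .sequence import (
    PeptideSequence,
    charge_profile,
    composition_summary,
    das_pappu_classify,
    disorder_propensity_profile,
    extinction_coefficient_214,
    find_tm_segments,
    hydropathy_profile,
    isoelectric_point,
    min_tm_segment_length,
    parse_sequence,
    read_fasta,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a characterization run; unknown keys are rejected."""

    sequence: Optional[str] = None  # literal one-letter sequence
    sequence_path: Optional[str] = None  # FASTA file
    ensemble_path: Optional[str] = None  # multi-model PDB
    output_dir: str = "idpchar_out"
    # sequence-stage parameters
    pH: float = 7.4
    hydropathy_window: int = 5
    hydropathy_scale: str = "ww_octanol"
    ionization: str = "physiological"
    coupling_per_residue: float = 0.4
    bilayer_thickness: float = 30.0
    # generator parameters
    n_frames: int = 200
    seed: int = 0
    basin_weights: Optional[Mapping[str, float]] = None
    mean_run_length: float = 6.0
    clash_distance: float = 3.0
    # ensemble-analysis parameters
    cluster_cutoffs: tuple[float, ...] = (0.99, 0.70, 0.50)
    contact_cutoff: float = 4.0
    neighbor_exclusion: int = 2
    ramachandran_bin: float = 10.0
    pr_bin_width: float = 0.5
    q_min: float = 0.005
    q_max: float = 0.40
    n_q: int = 120
    qrg_limit: float = 0.8
    max_cluster_frames: int = 200

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        if "cluster_cutoffs" in data:
            data["cluster_cutoffs"] = tuple(float(c) for c in data["cluster_cutoffs"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def resolve_sequence(self) -> PeptideSequence:
        if self.sequence_path:
            return read_fasta(self.sequence_path)
        if self.sequence:
            return parse_sequence(self.sequence)
        raise ValueError("no sequence configured (set sequence or sequence_path)")


def _stamp(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _profile_frame(seq: PeptideSequence, profile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position_1based": np.arange(1, len(seq) + 1),
            "residue": list(seq.residues),
            "value": profile.as_array(),
            "defined_flag": [int(d) for d in profile.defined],
        }
    )


def sequence_summary(config: RunConfig) -> dict:
    """All sequence-level quantities as one JSON-serializable dict."""
    seq = config.resolve_sequence()
    comp = composition_summary(seq)
    dp = das_pappu_classify(seq)
    part = partition_free_energy(
        seq, ionization=config.ionization,
        per_residue_coupling=config.coupling_per_residue,
    )
    hyd = hydropathy_profile(seq, config.hydropathy_window, config.hydropathy_scale)
    min_len_helix = min_tm_segment_length(config.bilayer_thickness, 1.5)
    min_len_strand = min_tm_segment_length(config.bilayer_thickness, 3.3)
    segments = find_tm_segments(hyd, min_length=min_len_helix)
    return {
        **_stamp(config),
        "name": seq.name,
        "sequence": seq.residues,
        "length": len(seq),
        "n_positive": comp.n_positive,
        "n_negative": comp.n_negative,
        "molecular_weight_da": round(comp.molecular_weight, 2),
        "molecular_weight_kda": round(comp.molecular_weight / 1000.0, 3),
        "net_charge_integer": charge_profile(seq, config.pH, "integer").net_charge,
        "net_charge_hh": round(
            charge_profile(seq, config.pH, "henderson_hasselbalch").net_charge, 3
        ),
        "pH": config.pH,
        "isoelectric_point": isoelectric_point(seq),
        "das_pappu": {
            "f_plus": round(dp.f_plus, 4),
            "f_minus": round(dp.f_minus, 4),
            "FCR": round(dp.FCR, 4),
            "NCPR": round(dp.NCPR, 4),
            "region": dp.region,
        },
        "epsilon_214_per_M_cm": extinction_coefficient_214(seq),
        "partitioning": {
            "ionization": part.ionization,
            "total_dG_kcal_mol": round(part.total_dG, 2),
            "terminal_dG_kcal_mol": [round(v, 2) for v in part.terminal_dG],
            "folding_coupled_dG_kcal_mol": round(part.folding_coupled_dG, 2),
            "coupling_per_residue": config.coupling_per_residue,
        },
        "transmembrane": {
            "bilayer_thickness_A": config.bilayer_thickness,
            "min_segment_length_helix": min_len_helix,
            "min_segment_length_strand": min_len_strand,
            "segments_found": [list(s) for s in segments],
        },
    }


def run_sequence_report(config: RunConfig) -> Path:
    """Emit the sequence-level JSON summary plus per-position TSV profiles.

    Returns the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = config.resolve_sequence()
    _write_json(out / "sequence_summary.json", sequence_summary(config))

    cp = charge_profile(seq, config.pH, "henderson_hasselbalch")
    charge_df = pd.DataFrame(
        {
            "position_1based": np.arange(1, len(seq) + 1),
            "residue": list(seq.residues),
            "value": cp.per_position_charge,
            "defined_flag": 1,
        }
    )
    charge_df.to_csv(out / "charge_profile.tsv", sep="\t", index=False)
    _profile_frame(seq, disorder_propensity_profile(seq)).to_csv(
        out / "disorder_propensity.tsv", sep="\t", index=False
    )
    _profile_frame(
        seq, hydropathy_profile(seq, config.hydropathy_window, config.hydropathy_scale)
    ).to_csv(out / "hydropathy_profile.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# Ensemble stage
# ---------------------------------------------------------------------------


def _resolve_ensemble(config: RunConfig) -> Ensemble:
    if config.ensemble_path:
        return read_ensemble(config.ensemble_path)
    seq = config.resolve_sequence()
    mixture = DEFAULT_DISORDERED_MIXTURE
    if config.basin_weights:
        mixture = BasinMixture(
            weights=dict(config.basin_weights),
            mean_run_length=config.mean_run_length,
        )
    return sample_ensemble(
        seq,
        mixture,
        n_frames=config.n_frames,
        seed=config.seed,
        clash_distance=config.clash_distance,
    )


def generate_ensemble(config: RunConfig, pdb_path) -> Path:
    """Generate a synthetic ensemble, write it as multi-model PDB plus a
    provenance JSON next to it."""
    ens = _resolve_ensemble(config)
    pdb_path = Path(pdb_path)
    pdb_path.parent.mkdir(parents=True, exist_ok=True)
    write_ensemble(pdb_path, ens)
    _write_json(
        pdb_path.with_suffix(".provenance.json"),
        {**_stamp(config), **dict(ens.provenance)},
    )
    return pdb_path


def run_ensemble_report(config: RunConfig) -> Path:
    """Full structural + SAXS report of an ensemble (generated or read)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ens = _resolve_ensemble(config)

    # chain dimensions (Angstrom internally, reported in nm)
    rg = conf.radius_of_gyration(ens)
    ree = conf.end_to_end(ens)
    pd.DataFrame(
        {"frame": np.arange(len(ens)), "rg_nm": rg / 10.0, "ree_nm": ree / 10.0}
    ).to_csv(out / "chain_dimensions.tsv", sep="\t", index=False)

    diag = {}
    for name, series in (("Rg", rg), ("Ree", ree)):
        d = conf.series_diagnostics(series, name)
        diag[name] = {
            "acf_first_lags": [round(float(v), 4) for v in d.acf[:6]],
            "block_sizes": d.block_sizes.tolist(),
            "block_se_nm": [round(float(v) / 10.0, 5) for v in d.block_se],
        }

    dm = conf.distance_map(ens)
    np.savetxt(out / "distance_map.tsv", dm.matrix, delimiter="\t", fmt="%.3f")
    cm = conf.contact_map(
        ens, cutoff=config.contact_cutoff,
        neighbor_exclusion=config.neighbor_exclusion,
    )
    np.savetxt(out / "contact_map.tsv", cm.matrix, delimiter="\t", fmt="%.4f")

    ss = conf.assign_secondary_structure(ens)
    rama = conf.ramachandran_histogram(ens, bin=config.ramachandran_bin)
    np.savetxt(out / "ramachandran_counts.tsv", rama.counts, delimiter="\t", fmt="%d")

    # clustering at each configured cutoff (capped frame count keeps the
    # quadratic RMSD matrix small; frames are subsampled evenly if needed)
    n_cluster = min(len(ens), config.max_cluster_frames)
    idx = np.linspace(0, len(ens) - 1, n_cluster).astype(int)
    sub = Ensemble(
        ens.coords[idx], ens.sequence, ens.atom_names,
        weights=ens.weights[idx],
    )
    rmsd_mat = conf.pairwise_rmsd_matrix(sub)
    clusters = {}
    for cutoff in config.cluster_cutoffs:
        res = conf.gromos_cluster(sub, cutoff=cutoff, rmsd_matrix=rmsd_mat)
        clusters[f"{cutoff:.2f}"] = {
            "n_clusters": res.n_clusters,
            "populations_percent": [round(p, 2) for p in res.populations],
            "representative_frames": [int(idx[r]) for r in res.representatives],
        }

    # SAXS-style analysis
    q = np.linspace(config.q_min, config.q_max, config.n_q)
    curve = saxs.debye_curve(ens, q)
    saxs.write_curve(out / "debye_curve.dat", curve)
    saxs.write_curve(out / "kratky.dat", saxs.kratky_transform(curve))
    fit = saxs.guinier_fit(curve, qrg_limit=config.qrg_limit)
    pr = saxs.pr_from_coordinates(ens, bin_width=config.pr_bin_width)
    pd.DataFrame({"r_A": pr.r, "P": pr.P}).to_csv(
        out / "pr_distribution.tsv", sep="\t", index=False
    )

    report = {
        **_stamp(config),
        "sequence": ens.sequence.residues,
        "n_frames": len(ens),
        "provenance": dict(ens.provenance),
        "rg_nm": {
            "mean": round(float(np.average(rg, weights=ens.weights)) / 10.0, 4),
            "sd": round(float(np.sqrt(np.average(
                (rg - np.average(rg, weights=ens.weights)) ** 2,
                weights=ens.weights))) / 10.0, 4),
        },
        "ree_nm": {
            "mean": round(float(np.average(ree, weights=ens.weights)) / 10.0, 4),
            "sd": round(float(np.sqrt(np.average(
                (ree - np.average(ree, weights=ens.weights)) ** 2,
                weights=ens.weights))) / 10.0, 4),
        },
        "convergence": diag,
        "secondary_structure_fractions": {
            k: round(v, 4) for k, v in ss.fractions().items()
        },
        "ramachandran_total_count": rama.total,
        "pca_explained_variance": [
            round(float(v), 4)
            for v in conf.pca_backbone(ens).explained_variance_ratio
        ],
        "clusters": clusters,
        "saxs": {
            "guinier_rg_nm": round(fit.rg_nm, 4),
            "guinier_rg_A": round(fit.rg, 3),
            "guinier_I0": round(fit.I0, 3),
            "guinier_n_points": fit.n_points,
            "guinier_q_range": [round(v, 5) for v in fit.q_range_used],
            "pr_rg_nm": round(pr.rg() / 10.0, 4),
            "pr_dmax_nm": round(pr.Dmax / 10.0, 3),
        },
    }
    _write_json(out / "ensemble_report.json", report)
    return out
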