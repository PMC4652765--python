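"""Readers and writers for the formats the package touches.

FASTA in/out goes through Biopython.  Motifs serialize to BED6 (0-based
half-open, score = rounded predicted dsDNA folded percent, name = loop
profile) and to a JSON report.  Emission spectra use a two-column CSV
(``wavelength_nm,intensity``) with a manifest CSV tying samples to files.
Simulated trace datasets are stored as one tabular CSV per field of view
(``molecule_id,frame,time_s,donor,acceptor``) plus a JSON sidecar holding
the generative config, red-pulse records and truth labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import GQMotif
from .rules import ConformationCall, RuleTable, predict_ds_folded_fraction
from .spectra import CDSpectrum, EmissionSpectrum
from .simulate import Trace, TraceDataset, TraceSimConfig, TraceTruth

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "write_motif_report",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectra_manifest",
    "read_cd_spectrum_csv",
    "write_trace_store",
    "read_trace_store",
    "write_json",
]


# -- FASTA -----------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record) FASTA; sequences are uppercased."""
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# -- BED / motif reports ----------------------------------------------------

def write_bed(
    motifs: Sequence[GQMotif], path, rules: Optional[RuleTable] = None
) -> None:
    """BED6: name = loop profile, score = rounded predicted ds folded percent."""
    with open(path, "w") as fh:
        for m in motifs:
            score = int(round(predict_ds_folded_fraction(m, rules)))
            fh.write(
                f"{m.sequence_id}\t{m.start}\t{m.end}\t{m.loop_profile}"
                f"\t{score}\t{m.strand}\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            rows.append((chrom, int(start), int(end), name, int(score), strand))
    return rows


def write_motif_report(
    calls: Sequence[tuple[GQMotif, ConformationCall]], path
) -> None:
    payload = [
        {"motif": asdict(m), "call": asdict(c)} for m, c in calls
    ]
    write_json(payload, path)


# -- spectra CSV ------------------------------------------------------------

def read_spectrum_csv(
    path, ligand: str = "none", excitation_nm: float = 0.0, sample_id: str = ""
) -> EmissionSpectrum:
    df = pd.read_csv(path)
    if not {"wavelength_nm", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns wavelength_nm,intensity")
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        excitation_nm=excitation_nm,
        ligand=ligand,
        sample_id=sample_id or Path(path).stem,
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectra_manifest(manifest_path) -> list[EmissionSpectrum]:
    """Manifest CSV columns: sample_id, ligand, excitation_nm, file (relative
    to the manifest's directory)."""
    base = Path(manifest_path).parent
    df = pd.read_csv(manifest_path)
    required = {"sample_id", "ligand", "excitation_nm", "file"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return [
        read_spectrum_csv(
            base / row["file"],
            ligand=row["ligand"],
            excitation_nm=float(row["excitation_nm"]),
            sample_id=row["sample_id"],
        )
        for _, row in df.iterrows()
    ]


def read_cd_spectrum_csv(path, sample_id: str = "") -> CDSpectrum:
    df = pd.read_csv(path)
    wcol = "wavelength_nm" if "wavelength_nm" in df.columns else df.columns[0]
    ycol = "ellipticity" if "ellipticity" in df.columns else df.columns[1]
    return CDSpectrum(
        wavelengths=df[wcol].to_numpy(float),
        ellipticity=df[ycol].to_numpy(float),
        sample_id=sample_id or Path(path).stem,
    )


# -- trace store -------------------------------------------------------------

def write_trace_store(dataset: TraceDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {
        "config": dataset.config.to_dict(),
        "field_of_molecule": dataset.field_of_molecule.tolist(),
        "molecules": {},
    }
    for fov in range(dataset.n_fields):
        traces = dataset.field_traces(fov)
        frames = []
        for t in traces:
            frames.append(
                pd.DataFrame(
                    {
                        "molecule_id": t.molecule_id,
                        "frame": np.arange(len(t.time)),
                        "time_s": t.time,
                        "donor": t.donor,
                        "acceptor": t.acceptor,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"field_{fov:03d}.csv", index=False
        )
    for t in dataset.traces:
        entry: dict = {"red_pulse_acceptor": np.round(t.red_pulse_acceptor, 6).tolist()}
        if t.truth is not None:
            entry["truth"] = {
                "class": t.truth.class_,
                "state_path": t.truth.state_path.astype(int).tolist(),
                "donor_bleach_frame": t.truth.donor_bleach_frame,
                "acceptor_bleach_frame": t.truth.acceptor_bleach_frame,
            }
        sidecar["molecules"][str(t.molecule_id)] = entry
    write_json(sidecar, outdir / "manifest.json")


def read_trace_store(indir) -> TraceDataset:
    indir = Path(indir)
    manifest_path = indir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {indir}: not a trace store")
    with open(manifest_path) as fh:
        sidecar = json.load(fh)
    config = TraceSimConfig.from_dict(sidecar["config"])
    field_of_molecule = np.asarray(sidecar["field_of_molecule"], dtype=np.int64)
    traces: dict[int, Trace] = {}
    for csv_path in sorted(indir.glob("field_*.csv")):
        df = pd.read_csv(csv_path)
        for mol_id, grp in df.groupby("molecule_id", sort=True):
            entry = sidecar["molecules"][str(int(mol_id))]
            truth = None
            if "truth" in entry:
                t = entry["truth"]
                truth = TraceTruth(
                    class_=t["class"],
                    state_path=np.asarray(t["state_path"], dtype=np.int8),
                    donor_bleach_frame=t["donor_bleach_frame"],
                    acceptor_bleach_frame=t["acceptor_bleach_frame"],
                )
            traces[int(mol_id)] = Trace(
                molecule_id=int(mol_id),
                time=grp["time_s"].to_numpy(float),
                donor=grp["donor"].to_numpy(float),
                acceptor=grp["acceptor"].to_numpy(float),
                red_pulse_acceptor=np.asarray(entry["red_pulse_acceptor"], float),
                truth=truth,
            )
    ordered = [traces[i] for i in sorted(traces)]
    return TraceDataset(
        traces=ordered, field_of_molecule=field_of_molecule, config=config
    )


# -- generic helpers ---------------------------------------------------------

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, cls=_NumpyEncoder)
        fh.write("\n")


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
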