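"""Readers and writers for the pipeline's plain-text formats.

Spectra travel as two-column TSV (m/z, intensity) with a commented
header naming units; ladders, assignments and compositions as TSV with
``#`` headers; probes and run manifests as JSON; sequences as FASTA
(via Biopython).  A minimal mzML reader (first MS1 scan set) is
provided for instrument exports.
"""

from __future__ import annotations

import base64
import json
import struct
import sys
import zlib
from datetime import datetime, timezone
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ladder import MassLadder
from .probe import ProbeDesign
from .spectrum import CompositionEstimate, Spectrum

__all__ = [
    "write_spectrum_tsv", "read_spectrum_tsv", "read_mzml",
    "write_ladder_tsv", "write_assignments_tsv",
    "write_composition", "read_composition_table",
    "write_fasta", "write_manifest",
]


def write_spectrum_tsv(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: mz (Th), intensity (arbitrary units)\n")
        for k, v in sorted(spectrum.metadata.items()):
            fh.write(f"# {k}: {json.dumps(v)}\n")
        for mz, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f}\t{y:.6f}\n")


def read_spectrum_tsv(path) -> Spectrum:
    meta = {}
    mzs, ys = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body and not body.startswith("columns"):
                    k, v = body.split(":", 1)
                    try:
                        meta[k.strip()] = json.loads(v.strip())
                    except json.JSONDecodeError:
                        meta[k.strip()] = v.strip()
                continue
            a, b = line.split("\t")
            mzs.append(float(a))
            ys.append(float(b))
    return Spectrum(np.array(mzs), np.array(ys), meta)


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary(elem) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (zlib optional, 32/64-bit floats)."""
    dtype = "<d"
    compressed = False
    for cv in elem.iter(f"{_NS}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f"
        elif acc == "MS:1000523":
            dtype = "<d"
        elif acc == "MS:1000574":
            compressed = True
    node = elem.find(f"{_NS}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    n = len(raw) // struct.calcsize(dtype)
    return np.array(struct.unpack("<" + dtype[-1] * n, raw))


def read_mzml(path) -> Spectrum:
    """First MS1 scan of an mzML file as a Spectrum."""
    tree = ElementTree.parse(path)
    for spec in tree.iter(f"{_NS}spectrum"):
        ms_level = None
        for cv in spec.findall(f"{_NS}cvParam"):
            if cv.get("accession") == "MS:1000511":
                ms_level = int(cv.get("value", "0"))
        if ms_level not in (None, 1):
            continue
        arrays = {}
        for bda in spec.iter(f"{_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall(f"{_NS}cvParam")}
            data = _decode_binary(bda)
            if "MS:1000514" in accs:
                arrays["mz"] = data
            elif "MS:1000515" in accs:
                arrays["intensity"] = data
        if "mz" in arrays and "intensity" in arrays:
            order = np.argsort(arrays["mz"])
            return Spectrum(arrays["mz"][order], np.clip(arrays["intensity"][order], 0, None),
                            {"source": str(path), "format": "mzML"})
    raise ValueError(f"no MS1 spectrum with m/z and intensity arrays in {path}")


def write_ladder_tsv(ladder: MassLadder, path) -> None:
    with open(path, "w") as fh:
        fh.write("# theoretical mass ladder; neutral masses in Da, m/z per charge state\n")
        fh.write(f"# window: {ladder.window[0]}-{ladder.window[1]} m/z; "
                 f"charges {ladder.charge_range[0]}-{ladder.charge_range[1]}\n")
        fh.write("class\tnon_repair\theavy_removed\tmono_mass\tavg_mass\tmz_by_charge\n")
        for e in ladder.entries:
            mzs = ";".join(f"{z}:{mz:.4f}" for z, mz in sorted(e.mz_by_charge.items()))
            fh.write(f"{e.label}\t{int(e.non_repair)}\t{e.outcome.heavy_removed}\t"
                     f"{e.mass.monoisotopic:.4f}\t{e.mass.average:.4f}\t{mzs}\n")


def write_assignments_tsv(assignments, peaks, path) -> None:
    with open(path, "w") as fh:
        fh.write("# peak assignments; mass error in Da at neutral level\n")
        fh.write("peak_mz\theight\tclass\tcharge\tmass_error_da\tmass_error_ppm\tambiguous\n")
        for a in assignments:
            fh.write(
                f"{peaks.centroid_mz[a.peak_index]:.4f}\t{peaks.height[a.peak_index]:.2f}\t"
                f"{a.label}\t{a.charge}\t{a.mass_error_da:.4f}\t"
                f"{a.mass_error_ppm:.1f}\t{int(a.ambiguous)}\n"
            )


def write_composition(estimate: CompositionEstimate, path, fmt: str = "tsv") -> None:
    if fmt == "json":
        payload = {
            "proportions": estimate.as_dict(),
            "heights": {lab: float(h) for lab, h in zip(estimate.labels, estimate.heights)},
            "unrepaired_fraction": estimate.unrepaired_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
        return
    with open(path, "w") as fh:
        fh.write("# repair-product composition; proportions on [0,1] over repair classes\n")
        fh.write(f"# unrepaired_fraction: {estimate.unrepaired_fraction:.6f}\n")
        fh.write("class\theight\tproportion\n")
        for lab, h, p in zip(estimate.labels, estimate.heights, estimate.proportions):
            fh.write(f"{lab}\t{h:.4f}\t{p:.6f}\n")


def read_composition_table(path) -> pd.DataFrame:
    """Replicate composition table: TSV with a group column and one
    column per class (comment lines allowed)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_composition_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# replicate compositions; proportions on [0,1]\n")
        df.to_csv(fh, sep="\t", index=False)


def write_fasta(design: ProbeDesign, path) -> None:
    rec = SeqRecord(Seq(design.sequence), id=design.name,
                    description=f"topology={design.topology} lesion@{design.lesion_index}")
    SeqIO.write([rec], path, "fasta")


def write_manifest(path, command: str, seed: int | None, config: dict,
                   inputs=None, outputs=None) -> None:
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": list(inputs or []),
        "outputs": list(outputs or []),
        "tool": "berpatch",
        "version": _version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": sys.version.split()[0],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def _version() -> str:
    from . import __version__

    return __version__
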