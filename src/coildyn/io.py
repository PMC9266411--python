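"""File formats and run configuration.

Plain-text formats only: 3-column SAS ``.dat`` files (q, I, sigma; '#'
comments, SasView dialect), 4-column NSE ASCII (q, t, I/I0, sigma; optional
'# q =' block headers), Cα-only PDB ensembles (MODEL/ENDMDL blocks, the
occupancy column carrying the population weight) via gemmi, and a YAML run
configuration with a provenance record.

q values are Å⁻¹ internally; readers accept nm⁻¹ with ``q_unit="1/nm"``
and convert on read (factor 0.1).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .chains import BeadChain, Ensemble
from .sas import ScatteringCurve, StructureFactorCurve
from .zimm import NSEDataset

__all__ = [
    "read_sas",
    "write_sas",
    "read_nse",
    "write_nse",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "RunConfig",
]

_Q_FACTORS = {"1/A": 1.0, "1/nm": 0.1}


def _q_factor(q_unit: str) -> float:
    try:
        return _Q_FACTORS[q_unit]
    except KeyError:
        raise ValueError(f"unknown q unit {q_unit!r}; use '1/A' or '1/nm'") from None


def _parse_columns(path, n_cols: int):
    rows, meta = [], {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if "=" in body or ":" in body:
                key, _, val = body.replace(":", "=", 1).partition("=")
                if key.strip():
                    meta.setdefault(key.strip(), val.strip())
            continue
        parts = s.split()
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}, line {lineno}: expected {n_cols} columns, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ValueError(f"{path}, line {lineno}: non-numeric value") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.array(rows), meta


def read_sas(path, q_unit: str = "1/A") -> ScatteringCurve:
    """Read a 3-column (q, I, sigma) ASCII file."""
    data, meta = _parse_columns(path, 3)
    q = data[:, 0] * _q_factor(q_unit)
    order = np.argsort(q)
    return ScatteringCurve(q[order], data[order, 1], data[order, 2], meta=meta)


def write_sas(path, curve: ScatteringCurve | StructureFactorCurve) -> None:
    """Write a (q, I, sigma) or (q, S, sigma) curve as 3-column ASCII."""
    y = curve.I if isinstance(curve, ScatteringCurve) else curve.S
    with open(path, "w") as fh:
        for key, val in curve.meta.items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# q [1/A]  I  sigma\n")
        for row in zip(curve.q, y, curve.sigma):
            fh.write("  ".join(f"{v:.8e}" for v in row) + "\n")


def read_nse(path, q_unit: str = "1/A") -> NSEDataset:
    """Read NSE ASCII: 4 columns (q, t, I/I0, sigma) or 3 columns inside
    '# q = <value>' blocks."""
    text = Path(path).read_text().splitlines()
    has_blocks = any(l.strip().lower().startswith(("# q =", "# q=", "#q=")) for l in text)
    f = _q_factor(q_unit)
    if not has_blocks:
        data, meta = _parse_columns(path, 4)
        return NSEDataset.from_arrays(data[:, 0] * f, data[:, 1],
                                      data[:, 2], data[:, 3], meta=meta)
    rows, meta, q_cur = [], {}, None
    for lineno, line in enumerate(text, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip().replace(" ", "")
            if body.lower().startswith("q="):
                q_cur = float(body[2:]) * f
            continue
        if q_cur is None:
            raise ValueError(f"{path}, line {lineno}: data before any '# q =' header")
        parts = s.split()
        if len(parts) == 4:            # q column repeated inside the block
            parts = parts[1:]
        if len(parts) != 3:
            raise ValueError(f"{path}, line {lineno}: expected 3 or 4 columns in q-block")
        rows.append([q_cur, *(float(p) for p in parts)])
    arr = np.array(rows)
    return NSEDataset.from_arrays(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], meta=meta)


def write_nse(path, ds: NSEDataset) -> None:
    """Write an NSE dataset as 4-column ASCII with q-block comments."""
    with open(path, "w") as fh:
        for key, val in ds.meta.items():
            if isinstance(val, (str, int, float, bool)):
                fh.write(f"# {key} = {val}\n")
        fh.write("# q [1/A]  t [ns]  I/I0  sigma\n")
        for q, t, I, sig in ds.groups():
            fh.write(f"# q = {q:.6g}\n")
            for row in zip([q] * t.size, t, I, sig):
                fh.write("  ".join(f"{v:.8e}" for v in row) + "\n")


# --------------------------------------------------------------------------- #
# PDB ensembles
# --------------------------------------------------------------------------- #

def write_pdb_ensemble(path, ens: Ensemble) -> None:
    """Write conformers as CA-only MODEL/ENDMDL blocks.

    Residues are numbered from 1; the occupancy column carries the
    population weight of the model.
    """
    st = gemmi.Structure()
    st.name = "coildyn ensemble"
    for imodel, (chain, w) in enumerate(zip(ens.chains, ens.weights), start=1):
        model = gemmi.Model(imodel)
        ch = gemmi.Chain("A")
        for i, xyz in enumerate(chain.coords, start=1):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = float(w)
            atom.b_iso = 0.0
            res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def read_pdb_ensemble(path, bond: float = 3.8) -> Ensemble:
    """Read a CA-only multi-MODEL PDB into an ensemble.

    Population weights are taken from the occupancy column (renormalized);
    uniform weights are assumed when occupancies are absent or all equal.
    """
    st = gemmi.read_structure(str(path))
    chains, weights = [], []
    for model in st:
        coords, occ = [], []
        for ch in model:
            for res in ch:
                for atom in res:
                    if atom.name == "CA":
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        occ.append(atom.occ)
        if not coords:
            raise ValueError(f"{path}: model {model.num} has no CA atoms")
        chains.append(BeadChain(np.array(coords), bond=bond))
        weights.append(occ[0] if occ else 1.0)
    if not chains:
        raise ValueError(f"{path}: no models found")
    w = np.array(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(chains))
    return Ensemble(chains, w)


# --------------------------------------------------------------------------- #
# run configuration
# --------------------------------------------------------------------------- #

@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Synthetic runs leave the input paths empty and generate the condition
    series internally; file-based runs point at measured curves.  Every run
    writes a provenance record (config + seed + package version) next to
    its outputs.
    """

    seed: int = 0
    outdir: str = "coildyn_out"
    # fixed physical inputs
    T: float = 295.0              # [K]
    eta: float = 1.1              # solvent viscosity [mPa·s]
    D0t: float | None = None      # [Å²/ns]; None -> bead-model estimate
    # model choices
    n_beads_zimm: int = 20
    n_modes: int = 10
    guinier_limit: float = 1.3
    q_unit: str = "1/A"
    noise_frac: float = 0.02
    n_chains: int = 40
    # optional file inputs (synthetic series when absent)
    saxs_path: str | None = None
    sq_path: str | None = None
    nse_path: str | None = None
    ensemble_path: str | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra.update(unknown)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def provenance(self) -> dict:
        from . import __version__
        return {
            "config": asdict(self),
            "coildyn_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        }
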