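"""Readers/writers for simulator outputs: VCF, delimited matrices, TSV
tables, JSON parameter records, and run provenance."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "write_vcf",
    "read_vcf_haplotypes",
    "write_matrix",
    "read_matrix",
    "write_pheno_tsv",
    "write_architecture_tsv",
    "write_params_json",
    "load_config",
    "write_provenance",
]

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length={length}>\n"
)


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, *, path=None, line: int | None = None):
        where = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{where}: {message}" if where else message)
        self.path = path
        self.line = line


def write_vcf(result, path) -> None:
    """Write a simulation result as a minimal plain-text VCF 4.2.

    Synthetic contig "1", positions 1..L (locus j at POS j, 1-based),
    REF=A/ALT=B placeholders, phased GT "h1|h2" where h1 is the haploid
    variant 2j-1 (1-based; the first column of the pair — an arbitrary but
    documented gamete order).
    """
    hap = np.asarray(result.haplotypes)
    if hap.size == 0:
        raise ValueError("refusing to write a VCF with no genotypes")
    n, m = hap.shape
    L = m // 2
    sample_names = [f"ind{i + 1}" for i in range(n)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(VCF_HEADER.format(length=L))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for j in range(L):
            gts = "\t".join(f"{hap[i, 2 * j]}|{hap[i, 2 * j + 1]}" for i in range(n))
            fh.write(f"1\t{j + 1}\tsnp{j + 1}\tA\tB\t.\t.\t.\tGT\t{gts}\n")


def read_vcf_haplotypes(path) -> np.ndarray:
    """Reconstruct the n x m haplotype matrix from a VCF written by
    :func:`write_vcf`, via pysam (an independent standard parser)."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        columns = []
        for rec in vf:
            alleles = np.array([rec.samples[s]["GT"] for s in samples], dtype=np.uint8)
            columns.append(alleles)
    if not columns:
        raise ParseError("VCF contains no variant records", path=path)
    return np.concatenate(columns, axis=1)


def write_matrix(path, M, *, delimiter: str = "\t") -> None:
    """Delimited-text matrix; integers written exactly, floats at full
    (round-trippable) precision."""
    M = np.asarray(M)
    if M.size == 0:
        raise ValueError("refusing to write an empty matrix")
    fmt = "%d" if np.issubdtype(M.dtype, np.integer) else "%.17g"
    np.savetxt(path, np.atleast_2d(M), fmt=fmt, delimiter=delimiter)


def read_matrix(path, *, dtype=float, delimiter: str = "\t") -> np.ndarray:
    try:
        M = np.loadtxt(path, dtype=dtype, delimiter=delimiter, ndmin=2)
    except ValueError as err:
        # numpy reports "... at line N" for malformed rows; surface it
        line = None
        msg = str(err)
        if "line " in msg:
            tail = msg.rsplit("line ", 1)[1]
            digits = "".join(ch for ch in tail if ch.isdigit())
            line = int(digits) if digits else None
        raise ParseError(msg, path=path, line=line) from err
    if M.size == 0:
        raise ParseError("file contains no data", path=path)
    return M


def write_pheno_tsv(path, g, y, ids=None) -> None:
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(g.shape[0])]
    pd.DataFrame({"id": ids, "g": g, "y": y}).to_csv(path, sep="\t", index=False)


def write_architecture_tsv(path, architecture) -> None:
    pd.DataFrame({
        "mu": architecture.mu,
        "beta": architecture.beta,
        "beta_allelic": architecture.beta_allelic,
        "phi": architecture.phi,
        "d": architecture.d,
    }).to_csv(path, sep="\t", index=False)


def write_params_json(path, params) -> None:
    payload = asdict(params) if is_dataclass(params) else dict(params)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_config(path) -> dict:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = json.load(fh)
    except json.JSONDecodeError as err:
        raise ParseError(err.msg, path=path, line=err.lineno) from err
    if not isinstance(cfg, dict):
        raise ParseError("config must be a JSON object", path=path)
    return cfg


def write_provenance(out_prefix, parameters: dict) -> Path:
    """Machine-readable record of a run: parameters, seed, package version."""
    path = Path(f"{out_prefix}.run.json")
    record = {"package": "bahadur", "version": _pkg_version("bahadur"),
              "parameters": parameters}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
    return path
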