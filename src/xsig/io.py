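"""Readers and writers for the package's plain-text formats.

Expression matrices travel as TSV (first column feature id, header sample
ids); annotations, homolog maps, designs, scores, survival and
dose-response tables as CSV; signatures as GMT (two sets per allele,
``<ALLELE>_UP`` and ``<ALLELE>_DN``) or two-column TSV; configurations as
YAML; ground truth as JSON. All writers use a fixed float format so that
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .signature import AlleleSignature

FLOAT_FMT = "%.10g"


def read_expression_tsv(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return m


def write_expression_tsv(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_annotation_csv(path) -> pd.Series:
    df = pd.read_csv(path, dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                     name="gene")


def write_annotation_csv(ann: pd.Series, path) -> None:
    pd.DataFrame({"probeset": ann.index, "gene": ann.values}).to_csv(
        path, index=False)


def read_homolog_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    df.columns = ["source", "target"] + list(df.columns[2:])
    return df[["source", "target"]]


def read_design_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_table_csv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, index=index)


def write_signatures_gmt(signatures: dict[str, AlleleSignature], path) -> None:
    with open(path, "w") as fh:
        for allele in sorted(signatures):
            sig = signatures[allele]
            fh.write("\t".join([f"{allele}_UP", f"allele {allele} up",
                                *sig.up_genes]) + "\n")
            fh.write("\t".join([f"{allele}_DN", f"allele {allele} down",
                                *sig.down_genes]) + "\n")


def read_signatures_gmt(path) -> dict[str, AlleleSignature]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    out: dict[str, AlleleSignature] = {}
    for name, genes in sets.items():
        if name.endswith("_UP"):
            allele = name[:-3]
            down = sets.get(f"{allele}_DN", [])
            out[allele] = AlleleSignature(allele, genes, down,
                                          {"source": str(path)})
    if not out:
        raise ValueError(f"no <allele>_UP/_DN set pairs found in {path}")
    return out


def write_signature_tsv(sig: AlleleSignature, path) -> None:
    rows = [{"gene": g, "direction": "up"} for g in sig.up_genes]
    rows += [{"gene": g, "direction": "down"} for g in sig.down_genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth, path) -> None:
    def enc(v):
        if isinstance(v, pd.DataFrame):
            return {c: v[c].tolist() for c in v.columns} | {"_index": list(v.index)}
        if isinstance(v, pd.Series):
            return {"index": list(v.index), "values": v.tolist()}
        if isinstance(v, dict):
            return {k: enc(x) for k, x in v.items()}
        if isinstance(v, (set, frozenset)):
            return sorted(v)
        return v

    payload = {k: enc(v) for k, v in vars(truth).items() if v is not None}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config_yaml(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
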