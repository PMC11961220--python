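"""File I/O: FASTA sequences, HDF5 embedding containers, label tables, reports.

The embedding container is the precomputed-embedding adapter: any frozen
language model can write per-protein token matrices into it offline, and
the pooling/training code only ever reads this container (or the
synthetic generator), so no model weights are needed at train time.

Layout: group ``/embeddings`` with one float32 dataset of shape n x d per
protein identifier; file attributes ``d``, ``source_model``, ``created``.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import TokenEmbeddingSet
from .metrics import MetricReport
from .synthetic import SyntheticDataset

__all__ = ["FastaParseError", "ContainerFormatError", "read_fasta",
           "write_embedding_container", "EmbeddingContainer",
           "write_label_table", "read_label_table", "export_dataset",
           "load_dataset", "write_metric_reports", "save_checkpoint",
           "load_checkpoint"]


class FastaParseError(ValueError):
    pass


class ContainerFormatError(ValueError):
    pass


def read_fasta(path) -> list:
    """Read (id, sequence) pairs; ids up to the first whitespace, sequences uppercased.

    Structural problems (no header, empty record) are reported with the
    offending line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header_line = None
    seen_seq = False
    any_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header_line is not None and not seen_seq:
                raise FastaParseError(f"empty record at line {header_line}")
            if len(line) == 1:
                raise FastaParseError(f"record without identifier at line {lineno}")
            header_line, seen_seq, any_header = lineno, False, True
        else:
            if not any_header:
                raise FastaParseError(f"sequence data before any '>' header at line {lineno}")
            seen_seq = True
    if not any_header:
        raise FastaParseError("no FASTA records found (no '>' header)")
    if header_line is not None and not seen_seq:
        raise FastaParseError(f"empty record at line {header_line}")
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


# ---------------------------------------------------------------------------
# embedding container

def write_embedding_container(path, proteins, *, source_model: str = "synthetic") -> None:
    """Write token-embedding matrices (32-bit floats) keyed by protein id."""
    proteins = list(proteins)
    if not proteins:
        raise ValueError("nothing to write")
    d = proteins[0].d
    with h5py.File(path, "w") as fh:
        fh.attrs["d"] = d
        fh.attrs["source_model"] = source_model
        fh.attrs["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        grp = fh.create_group("embeddings")
        for p in proteins:
            if p.d != d:
                raise ContainerFormatError(
                    f"inconsistent embedding dimension: {p.protein_id} has d={p.d}, expected {d}")
            grp.create_dataset(p.protein_id, data=p.embeddings.astype(np.float32))


class EmbeddingContainer:
    """Read-only view of an HDF5 embedding container."""

    def __init__(self, path):
        self.path = path
        self._fh = h5py.File(path, "r")
        if "embeddings" not in self._fh:
            raise ContainerFormatError(f"{path}: missing /embeddings group")
        self._grp = self._fh["embeddings"]
        self.d = int(self._fh.attrs.get("d", -1))
        self.source_model = str(self._fh.attrs.get("source_model", ""))

    def validate(self) -> None:
        for pid in self.keys():
            ds = self._grp[pid]
            if ds.ndim != 2 or ds.shape[1] != self.d:
                raise ContainerFormatError(
                    f"{self.path}: dataset {pid!r} has shape {ds.shape}, expected (*, {self.d})")

    def keys(self) -> list:
        return list(self._grp.keys())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._grp

    def __getitem__(self, protein_id: str) -> TokenEmbeddingSet:
        if protein_id not in self._grp:
            raise KeyError(f"protein id {protein_id!r} not in container {self.path}")
        return TokenEmbeddingSet(protein_id=protein_id,
                                 embeddings=np.asarray(self._grp[protein_id], dtype=np.float64))

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


# ---------------------------------------------------------------------------
# label / split table

def write_label_table(path, dataset: SyntheticDataset) -> None:
    """TSV with columns protein_id, label, split, length."""
    split_of = {}
    for name, idx in dataset.split.items():
        for i in idx:
            split_of[int(i)] = name
    rows = [{"protein_id": p.protein_id,
             "label": dataset.labels[i],
             "split": split_of[i],
             "length": p.n}
            for i, p in enumerate(dataset.proteins)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_label_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "label", "split", "length"} - set(df.columns)
    if missing:
        raise ContainerFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def export_dataset(dataset: SyntheticDataset, embeddings_path, labels_path,
                   drugs_path=None, *, source_model: str = "synthetic") -> None:
    """Write a generated dataset as HDF5 embeddings plus a TSV label/split table
    (and a fingerprint TSV when the dataset carries drugs)."""
    write_embedding_container(embeddings_path, dataset.proteins, source_model=source_model)
    write_label_table(labels_path, dataset)
    if dataset.drugs is not None:
        if drugs_path is None:
            raise ValueError("dataset has drug fingerprints but no drugs_path given")
        np.savetxt(drugs_path, dataset.drugs, fmt="%d", delimiter="\t")


def load_dataset(embeddings_path, labels_path, drugs_path=None) -> SyntheticDataset:
    """Reassemble a dataset from an embedding container and a label table."""
    df = read_label_table(labels_path)
    split = {name: np.array(sorted(df.index[df["split"] == name]))
             for name in ("train", "val", "test")}
    with EmbeddingContainer(embeddings_path) as cont:
        proteins = tuple(cont[pid] for pid in df["protein_id"])
    drugs = None
    if drugs_path is not None:
        drugs = np.loadtxt(drugs_path, delimiter="\t", ndmin=2)
    return SyntheticDataset(proteins=proteins,
                            labels=df["label"].to_numpy(),
                            split=split,
                            drugs=drugs)


# ---------------------------------------------------------------------------
# reports and checkpoints

def write_metric_reports(out_dir, reports: dict) -> None:
    """Emit metric reports as JSON plus a TSV (one row per seed, summary row last)."""
    import pathlib
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {name: rep.as_dict() for name, rep in reports.items()}
    (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2))
    rows = []
    for name, rep in reports.items():
        for i, v in enumerate(rep.per_seed):
            rows.append({"run": name, "metric": rep.metric_name, "seed_index": i,
                         "value": v})
        rows.append({"run": name, "metric": rep.metric_name, "seed_index": "summary",
                     "value": rep.mean, "std": rep.std})
    pd.DataFrame(rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)


def save_checkpoint(path, model, config_yaml: str | None = None) -> None:
    """Serialize the trainable arrays of a trained model plus a config snapshot."""
    from .train import _trainable
    with h5py.File(path, "w") as fh:
        fh.attrs["pooler"] = model.config.pooler
        fh.attrs["task"] = model.config.task
        if config_yaml is not None:
            fh.attrs["config_yaml"] = config_yaml
        grp = fh.create_group("params")
        for k, v in _trainable(model).items():
            grp.create_dataset(k, data=v)
        if model.pooler_params is not None and model.pooler_params.freeze_ref_and_slicers:
            # frozen arrays are part of the model even if not trainable
            grp.create_dataset("pool.slicers", data=model.pooler_params.slicers)
            grp.create_dataset("pool.ref_slices", data=model.pooler_params.ref_slices)


def load_checkpoint(path) -> dict:
    """Load checkpoint arrays into a plain dict (name -> array) plus attrs."""
    with h5py.File(path, "r") as fh:
        arrays = {k: np.asarray(v) for k, v in fh["params"].items()}
        attrs = dict(fh.attrs)
    return {"params": arrays, "attrs": attrs}
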