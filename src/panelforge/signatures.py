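"""Named protein panels (signatures) and the packaged benchmarking
registry: the 11-protein discovered panel (PPAV11) plus thirteen
published CSF signatures, all keyed by gene symbol."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional

__all__ = ["Signature", "load_signature_registry", "save_signature", "load_signature"]


@dataclass
class Signature:
    """An unweighted, ordered gene-symbol panel with provenance."""

    name: str
    gene_symbols: List[str]
    source: str = ""
    objective: str = ""
    discovery_method: str = ""
    notes: str = ""
    reported_auc: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError(f"signature {self.name!r}: gene list must be non-empty")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            dup = sorted({g for g in self.gene_symbols if self.gene_symbols.count(g) > 1})
            raise ValueError(f"signature {self.name!r}: duplicate symbols {dup}")

    def __len__(self) -> int:
        return len(self.gene_symbols)

    def to_dict(self) -> dict:
        return {
            "name": self.name, "genes": list(self.gene_symbols),
            "source": self.source, "objective": self.objective,
            "discovery_method": self.discovery_method, "notes": self.notes,
            "reported_auc": self.reported_auc,
        }


def _from_blob(blob: dict) -> Signature:
    return Signature(
        name=blob["name"], gene_symbols=list(blob["genes"]),
        source=blob.get("source", ""), objective=blob.get("objective", ""),
        discovery_method=blob.get("discovery_method", ""),
        notes=blob.get("notes", "") or "", reported_auc=blob.get("reported_auc"))


def load_signature_registry(path=None) -> List[Signature]:
    """Load the packaged registry (or a user-supplied JSON in the same
    schema)."""
    if path is None:
        text = resources.files("panelforge.data").joinpath("signatures.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    blob = json.loads(text)
    return [_from_blob(b) for b in blob["signatures"]]


def save_signature(sig: Signature, path) -> None:
    with open(path, "w") as fh:
        json.dump(sig.to_dict(), fh, indent=2)
        fh.write("\n")


def load_signature(path) -> Signature:
    with open(path) as fh:
        return _from_blob(json.load(fh))
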