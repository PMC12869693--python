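"""Single-file index container (versioned JSON).

Holds everything downstream queries need: the run-length BWT with its
samples, the frozen tag array, sequence metadata and the node-name table.
The sampled tag array is rebuilt on load (it is a cheap projection of the
tag array).  Loading refuses on magic/version mismatch; round trips are
bit-exact for all stored integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import IntegrityError
from .index import MSBWTIndex, TextCollection
from .tagarray import TagArray
from .translate import SampledTagArray, build_sampled

MAGIC = "pantag-index"
VERSION = 1


@dataclass
class IndexContainer:
    index: MSBWTIndex
    tags: TagArray
    node_names: dict[int, str]
    node_lengths: dict[int, int]
    report: dict | None = None

    def __post_init__(self):
        self.sampled: SampledTagArray = build_sampled(self.tags)

    def sid_of_name(self, name: str) -> int:
        return self.index.text.names.index(name)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        idx = self.index
        payload = {
            "magic": MAGIC,
            "version": VERSION,
            "sequences": idx.text.sequences,
            "names": idx.text.names,
            "rc_paired": idx.text.rc_paired,
            "run_chars": idx.run_chars.tolist(),
            "run_starts": idx.run_starts.tolist(),
            "C": idx.C.tolist(),
            "occ": idx.occ.reshape(-1).tolist(),
            "sample_first": idx.sample_first.tolist(),
            "sample_last": idx.sample_last.tolist(),
            "dollar_rows": sorted(idx.dollar_rows.items()),
            "phi_keys": idx.phi_keys.tolist(),
            "phi_vals": idx.phi_vals.tolist(),
            "tag_array": self.tags.to_dict(),
            "node_names": sorted(self.node_names.items()),
            "node_lengths": sorted(self.node_lengths.items()),
            "report": self.report,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, separators=(",", ":"))

    @classmethod
    def load(cls, path) -> "IndexContainer":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("magic") != MAGIC:
            raise IntegrityError(f"{path}: not a pantag index container")
        if d.get("version") != VERSION:
            raise IntegrityError(
                f"{path}: container version {d.get('version')} != supported {VERSION}"
            )
        text = TextCollection(d["sequences"], d["names"], d["rc_paired"])
        r = len(d["run_chars"])
        index = MSBWTIndex(
            text=text,
            run_chars=np.asarray(d["run_chars"], dtype=np.uint8),
            run_starts=np.asarray(d["run_starts"], dtype=np.int64),
            C=np.asarray(d["C"], dtype=np.int64),
            occ=np.asarray(d["occ"], dtype=np.int64).reshape(r, 6),
            sample_first=np.asarray(d["sample_first"], dtype=np.int64),
            sample_last=np.asarray(d["sample_last"], dtype=np.int64),
            dollar_rows={int(k): int(v) for k, v in d["dollar_rows"]},
            phi_keys=np.asarray(d["phi_keys"], dtype=np.int64),
            phi_vals=np.asarray(d["phi_vals"], dtype=np.int64),
        )
        return cls(
            index=index,
            tags=TagArray.from_dict(d["tag_array"]),
            node_names={int(k): v for k, v in d["node_names"]},
            node_lengths={int(k): int(v) for k, v in d["node_lengths"]},
            report=d.get("report"),
        )
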