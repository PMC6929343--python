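"""Embedded document collection for training illustrations.

Each illustration is stored as one JSON document with the key layout used by
the pipeline's NoSQL data model: ``_id`` (auto-generated integer), ``name``,
``shape``, ``pixels`` (9216 ints in 0..255) and ``landmark`` holding the
``coordinate_X`` / ``coordinate_Y`` arrays of the 34 point primitives.  The
collection serializes to JSON Lines (one document per line, UTF-8), which
keeps the schema intact while remaining file-backed and dependency-free.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .augmentation import SyntheticRecord


class DatastoreError(ValueError):
    pass


class IllustrationStore:
    """An insert-ordered collection of illustration documents."""

    def __init__(self) -> None:
        self._docs: list[dict] = []
        self._next_id = 1

    def __len__(self) -> int:
        return len(self._docs)

    def __iter__(self):
        return iter(self._docs)

    # -- writes -----------------------------------------------------------

    def insert(self, record: SyntheticRecord) -> int:
        """Validate and persist one record; return its auto-generated id.

        A record violating any invariant is rejected with the offending field
        named.  Duplicate names are allowed (names are labels, not keys) but
        trigger a warning.
        """
        problems = record.validate()
        if problems:
            raise DatastoreError(
                f"record rejected: invalid field(s) {', '.join(problems)}"
            )
        if any(d["name"] == record.name for d in self._docs):
            warnings.warn(f"duplicate record name {record.name!r}", stacklevel=2)
        doc = {
            "_id": self._next_id,
            "name": record.name,
            "shape": int(record.shape_id),
            "pixels": [int(v) for v in np.asarray(record.pixels)],
            "landmark": {
                "coordinate_X": [float(v) for v in record.coordinate_x],
                "coordinate_Y": [float(v) for v in record.coordinate_y],
            },
        }
        self._docs.append(doc)
        self._next_id += 1
        return doc["_id"]

    def insert_many(self, records) -> list[int]:
        return [self.insert(r) for r in records]

    # -- reads ------------------------------------------------------------

    def fetch(self, doc_id: int) -> dict:
        for d in self._docs:
            if d["_id"] == doc_id:
                return json.loads(json.dumps(d))  # defensive copy
        raise KeyError(f"no document with _id {doc_id}")

    def query_by_shape(self, shape_id: int) -> list[dict]:
        """All documents of one shape category, in insertion order."""
        return [json.loads(json.dumps(d)) for d in self._docs if d["shape"] == shape_id]

    def export_matrices(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Flatten the collection for learning.

        Returns ``(X, Y, names)`` where row i of ``X`` (n x 9216) holds
        document i's pixel values and row i of ``Y`` (n x 68) interleaves its
        landmark coordinates as (x0, y0, x1, y1, ..., x33, y33).  Row order is
        insertion order.
        """
        if not self._docs:
            raise DatastoreError("cannot export matrices from an empty collection")
        X = np.array([d["pixels"] for d in self._docs], dtype=np.int64)
        Y = np.empty((len(self._docs), 68), dtype=float)
        for i, d in enumerate(self._docs):
            Y[i, 0::2] = d["landmark"]["coordinate_X"]
            Y[i, 1::2] = d["landmark"]["coordinate_Y"]
        names = [d["name"] for d in self._docs]
        return X, Y, names

    def to_records(self) -> list[SyntheticRecord]:
        return [
            SyntheticRecord(
                name=d["name"],
                shape_id=d["shape"],
                pixels=np.asarray(d["pixels"], dtype=np.int64),
                coordinate_x=np.asarray(d["landmark"]["coordinate_X"], dtype=float),
                coordinate_y=np.asarray(d["landmark"]["coordinate_Y"], dtype=float),
            )
            for d in self._docs
        ]

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize as JSON Lines, one document per line."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for d in self._docs:
                fh.write(json.dumps(d, separators=(",", ":")) + "\n")

    @classmethod
    def load(cls, path) -> "IllustrationStore":
        store = cls()
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                doc = json.loads(line)
                store._docs.append(doc)
        if store._docs:
            store._next_id = max(d["_id"] for d in store._docs) + 1
        return store
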