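"""File-backed emulation of a private blockchain with named data streams.

The store mimics the stream semantics of permissioned-blockchain platforms
(MultiChain-style): named, append-only lists of key:value items, where every
publication is a transaction, transactions are batched into hash-linked
blocks, and per-key indexes enable fast retrieval.  It is a single-node,
single-process emulation: "nodes" are publisher identities with on-chain
permissions, not network peers.

On-disk layout (one directory per chain):

``header.json``
    Chain name, owner identity, digest algorithm, block size.  The digest
    algorithm is recorded so verification is self-describing.
``items.jsonl``
    Append-only log of published stream items, one JSON object per line, in
    publication order.  This file plus ``blocks.jsonl`` is the chain; the
    key index is derived data rebuilt on open.
``blocks.jsonl``
    Sealed blocks, one per line, heights consecutive from 0 (genesis).

Integrity model: each item's transaction id is a digest of its stored bytes
plus a chain-wide monotonic counter; each block's hash covers its height,
timestamp, ordered txid list and the previous block's hash.  Any single-byte
change to persisted item data or block metadata is therefore detectable by
:meth:`Chain.verify`.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Chain",
    "StreamItem",
    "Block",
    "IntegrityReport",
    "ChainError",
    "DuplicateStreamError",
    "UnknownStreamError",
    "InvalidKeyError",
    "PermissionDeniedError",
]

HASH_ALG = "sha256"
ZERO_DIGEST = "0" * 64

#: Reserved stream recording stream-creation transactions.
STREAMS_STREAM = "_streams"
#: Reserved stream recording permission grants/revocations.
PERMISSIONS_STREAM = "_permissions"

_ROLES = ("read", "write", "admin")


class ChainError(Exception):
    """Base class for chain-store errors."""


class DuplicateStreamError(ChainError):
    pass


class UnknownStreamError(ChainError):
    pass


class InvalidKeyError(ChainError):
    pass


class PermissionDeniedError(ChainError):
    pass


def _digest(data: bytes) -> str:
    return hashlib.new(HASH_ALG, data).hexdigest()


def valid_key(key: str) -> bool:
    """A key is 1-256 printable ASCII chars, no whitespace, no quotes."""
    if not 1 <= len(key) <= 256:
        return False
    for ch in key:
        o = ord(ch)
        if not 0x21 <= o <= 0x7E:  # printable, excludes space and controls
            return False
        if ch in ("'", '"'):
            return False
    return True


@dataclass(frozen=True)
class StreamItem:
    """One published record of a data stream.

    ``confirmations`` counts blocks sealed at or after the item's block and
    is computed at read time (0 while the transaction is pending); it is
    never persisted.
    """

    publisher: str
    keys: tuple[str, ...]
    data: bytes
    txid: str
    blocktime: int
    confirmations: int = 0


@dataclass(frozen=True)
class Block:
    height: int
    timestamp: int
    txids: tuple[str, ...]
    prev_hash: str
    hash: str


@dataclass(frozen=True)
class IntegrityReport:
    valid: bool
    first_bad_height: Optional[int] = None


def _item_txid(stream: str, publisher: str, keys: Iterable[str], data: bytes,
               counter: int, blocktime: int) -> str:
    # the digest covers every persisted field (blocktime included) so any
    # single-byte change to a stored item is tamper-evident; the monotonic
    # counter guarantees uniqueness for duplicate payloads
    payload = "\x1f".join(
        [stream, publisher, ",".join(sorted(keys)), data.hex(), str(counter),
         str(blocktime)]
    )
    return _digest(payload.encode("ascii"))


def _block_hash(height: int, timestamp: int, txids: Iterable[str],
                prev_hash: str) -> str:
    payload = json.dumps([height, timestamp, list(txids), prev_hash],
                         separators=(",", ":"))
    return _digest(payload.encode("ascii"))


@dataclass
class _StoredItem:
    stream: str
    publisher: str
    keys: tuple[str, ...]
    data: bytes
    counter: int
    blocktime: int
    txid: str


class Chain:
    """A file-backed hash-chained stream store.

    Use :meth:`create` to initialize a fresh chain directory and
    :meth:`open` to load an existing one.  All mutating operations append
    to the on-disk log immediately; blocks are sealed automatically every
    ``block_size`` pending transactions or explicitly via
    :meth:`mine_pending`.
    """

    def __init__(self, path: Path, header: dict):
        self.path = Path(path)
        self._header = header
        self._items: list[_StoredItem] = []
        self._blocks: list[Block] = []
        self._pending: list[str] = []          # txids awaiting sealing
        self._streams: dict[str, list[int]] = {}   # stream -> item ordinals
        self._key_index: dict[tuple[str, str], list[int]] = {}
        self._txid_height: dict[str, int] = {}
        self._counter = 0
        #: Streams touched by read operations; used to assert query locality.
        self.read_log: list[str] = []

    # ------------------------------------------------------------------
    # construction / persistence

    @classmethod
    def create(cls, path, name: str = "chain", owner: str = "owner",
               block_size: int = 1000) -> "Chain":
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        if (path / "header.json").exists():
            raise ChainError(f"chain already exists at {path}")
        header = {
            "name": name,
            "owner": owner,
            "hash_alg": HASH_ALG,
            "block_size": int(block_size),
            "created": int(time.time()),
        }
        (path / "header.json").write_text(
            json.dumps(header, sort_keys=True, indent=1) + "\n")
        (path / "items.jsonl").write_text("")
        (path / "blocks.jsonl").write_text("")
        chain = cls(path, header)
        # genesis block anchors the hash chain
        chain._append_block(timestamp=header["created"], txids=())
        chain._streams[STREAMS_STREAM] = []
        chain._streams[PERMISSIONS_STREAM] = []
        return chain

    @classmethod
    def open(cls, path) -> "Chain":
        path = Path(path)
        header = json.loads((path / "header.json").read_text())
        chain = cls(path, header)
        chain._streams[STREAMS_STREAM] = []
        chain._streams[PERMISSIONS_STREAM] = []
        for line in (path / "items.jsonl").read_text().splitlines():
            rec = json.loads(line)
            item = _StoredItem(
                stream=rec["stream"], publisher=rec["publisher"],
                keys=tuple(rec["keys"]), data=bytes.fromhex(rec["data"]),
                counter=rec["counter"], blocktime=rec["blocktime"],
                txid=rec["txid"])
            chain._index_item(item)
        for line in (path / "blocks.jsonl").read_text().splitlines():
            rec = json.loads(line)
            block = Block(rec["height"], rec["timestamp"],
                          tuple(rec["txids"]), rec["prev_hash"], rec["hash"])
            chain._blocks.append(block)
            for txid in block.txids:
                chain._txid_height[txid] = block.height
        chain._pending = [it.txid for it in chain._items
                          if it.txid not in chain._txid_height]
        return chain

    @property
    def owner(self) -> str:
        return self._header["owner"]

    @property
    def name(self) -> str:
        return self._header["name"]

    @property
    def height(self) -> int:
        return self._blocks[-1].height if self._blocks else -1

    def streams(self) -> list[str]:
        """All stream names in creation order (reserved streams first)."""
        return list(self._streams)

    # ------------------------------------------------------------------
    # internal plumbing

    def _index_item(self, item: _StoredItem) -> None:
        ordinal = len(self._items)
        self._items.append(item)
        self._counter = max(self._counter, item.counter + 1)
        if item.stream == STREAMS_STREAM:
            # a stream-creation record also registers the new stream
            self._streams.setdefault(item.data.decode("utf-8"), [])
        self._streams.setdefault(item.stream, []).append(ordinal)
        for key in item.keys:
            self._key_index.setdefault((item.stream, key), []).append(ordinal)

    def _write_item(self, item: _StoredItem) -> None:
        rec = {
            "stream": item.stream, "publisher": item.publisher,
            "keys": list(item.keys), "data": item.data.hex(),
            "counter": item.counter, "blocktime": item.blocktime,
            "txid": item.txid,
        }
        with (self.path / "items.jsonl").open("a") as fh:
            fh.write(json.dumps(rec, separators=(",", ":")) + "\n")

    def _append_block(self, timestamp: int, txids: tuple[str, ...]) -> Block:
        height = len(self._blocks)
        prev = self._blocks[-1].hash if self._blocks else ZERO_DIGEST
        block = Block(height, int(timestamp), tuple(txids), prev,
                      _block_hash(height, int(timestamp), txids, prev))
        self._blocks.append(block)
        for txid in block.txids:
            self._txid_height[txid] = height
        rec = {"height": block.height, "timestamp": block.timestamp,
               "txids": list(block.txids), "prev_hash": block.prev_hash,
               "hash": block.hash}
        with (self.path / "blocks.jsonl").open("a") as fh:
            fh.write(json.dumps(rec, separators=(",", ":")) + "\n")
        return block

    def _publish_raw(self, stream: str, publisher: str, keys, data: bytes,
                     blocktime: Optional[int] = None) -> str:
        keys = tuple(keys)
        for key in keys:
            if not valid_key(key):
                raise InvalidKeyError(
                    f"invalid key {key!r}: keys are 1-256 printable ASCII "
                    "characters excluding whitespace and quotes")
        blocktime = int(time.time()) if blocktime is None else int(blocktime)
        txid = _item_txid(stream, publisher, keys, data, self._counter,
                          blocktime)
        item = _StoredItem(stream, publisher, keys, data, self._counter,
                           blocktime, txid)
        self._index_item(item)
        self._write_item(item)
        self._pending.append(txid)
        if len(self._pending) >= self._header["block_size"]:
            self.mine_pending(timestamp=blocktime)
        return txid

    # ------------------------------------------------------------------
    # permissions

    def has_permission(self, identity: str, role: str) -> bool:
        """Effective permission: latest on-chain entry per (grantee, role).

        The chain owner implicitly holds every role.  Absent any entry,
        read access is open and write/admin are denied.
        """
        if role not in _ROLES:
            raise ChainError(f"unknown role {role!r}")
        if identity == self.owner:
            return True
        latest: Optional[bool] = None
        for ordinal in self._streams.get(PERMISSIONS_STREAM, ()):
            item = self._items[ordinal]
            entry = json.loads(item.data.decode("utf-8"))
            if entry["grantee"] == identity and entry["role"] == role:
                latest = bool(entry["granted"])
        if latest is None:
            return role == "read"
        return latest

    def set_permission(self, admin: str, grantee: str, role: str,
                       granted: bool, blocktime: Optional[int] = None) -> str:
        """Publish a grant/revoke entry to the reserved permissions stream."""
        if role not in _ROLES:
            raise ChainError(f"unknown role {role!r}")
        if not self.has_permission(admin, "admin"):
            raise PermissionDeniedError(f"{admin!r} is not an admin")
        entry = {"grantee": grantee, "role": role, "granted": bool(granted)}
        data = json.dumps(entry, sort_keys=True).encode("utf-8")
        return self._publish_raw(PERMISSIONS_STREAM, admin,
                                 (grantee, role), data, blocktime)

    # ------------------------------------------------------------------
    # streams

    def create_stream(self, name: str, caller: Optional[str] = None) -> str:
        """Create an empty named stream; returns the creation txid."""
        caller = self.owner if caller is None else caller
        if not (self.has_permission(caller, "write")
                or self.has_permission(caller, "admin")):
            raise PermissionDeniedError(f"{caller!r} cannot create streams")
        if not name or name.startswith("_"):
            raise ChainError(f"invalid stream name {name!r}")
        if name in self._streams:
            raise DuplicateStreamError(f"stream {name!r} already exists")
        return self._publish_raw(STREAMS_STREAM, caller, (name,),
                                 name.encode("utf-8"))

    def publish(self, stream: str, publisher: str, keys, data: bytes,
                blocktime: Optional[int] = None) -> str:
        """Append one item to a stream; the publication is a transaction."""
        if stream not in self._streams or stream.startswith("_"):
            raise UnknownStreamError(f"unknown stream {stream!r}")
        if not self.has_permission(publisher, "write"):
            raise PermissionDeniedError(f"{publisher!r} lacks write permission")
        if isinstance(data, str):
            data = data.encode("utf-8")
        return self._publish_raw(stream, publisher, keys, data, blocktime)

    def _confirmations(self, txid: str) -> int:
        height = self._txid_height.get(txid)
        if height is None:
            return 0
        return len(self._blocks) - height

    def _as_public(self, item: _StoredItem) -> StreamItem:
        return StreamItem(item.publisher, item.keys, item.data, item.txid,
                          item.blocktime, self._confirmations(item.txid))

    def _check_read(self, stream: str, caller: Optional[str]) -> None:
        if stream not in self._streams:
            raise UnknownStreamError(f"unknown stream {stream!r}")
        caller = self.owner if caller is None else caller
        if not self.has_permission(caller, "read"):
            raise PermissionDeniedError(f"{caller!r} lacks read permission")

    def list_stream_items(self, stream: str,
                          caller: Optional[str] = None) -> list[StreamItem]:
        """All items of a stream, in publication order."""
        self._check_read(stream, caller)
        self.read_log.append(stream)
        return [self._as_public(self._items[i])
                for i in self._streams[stream]]

    def list_stream_key_items(self, stream: str, key: str,
                              caller: Optional[str] = None) -> list[StreamItem]:
        """Items of a stream carrying ``key``, in publication order.

        An unused key yields an empty list, not an error.
        """
        self._check_read(stream, caller)
        self.read_log.append(stream)
        return [self._as_public(self._items[i])
                for i in self._key_index.get((stream, key), ())]

    # ------------------------------------------------------------------
    # mining / integrity

    def mine_pending(self, timestamp: Optional[int] = None) -> Optional[Block]:
        """Seal all pending transactions into a new block.

        Returns the new block, or ``None`` when nothing is pending.
        """
        if not self._pending:
            return None
        timestamp = int(time.time()) if timestamp is None else int(timestamp)
        txids = tuple(self._pending)
        self._pending = []
        return self._append_block(timestamp, txids)

    def free_bytes(self) -> int:
        """Free space on the filesystem holding the chain directory."""
        return shutil.disk_usage(self.path).free

    def verify(self) -> IntegrityReport:
        """Re-derive every digest from the persisted bytes.

        Checks, from disk and not from in-memory state: every block's hash
        and prev-hash link, consecutive heights from the genesis block, and
        every item's txid.  Corruption is reported with the height of the
        containing block (items are mined in publication order, so a
        malformed line is attributed by ordinal).
        """
        bad_heights: list[int] = []
        ok = True

        def raw_lines(name: str) -> list[bytes]:
            # byte-level split: a corrupted newline must merge lines rather
            # than silently re-splitting on another control character
            data = (self.path / name).read_bytes()
            lines = data.split(b"\n")
            if lines and lines[-1] == b"":
                lines.pop()
            return lines

        try:
            block_lines = raw_lines("blocks.jsonl")
            item_lines = raw_lines("items.jsonl")
        except OSError:
            return IntegrityReport(False, None)

        blocks: list[Optional[Block]] = []
        prev_hash = ZERO_DIGEST
        for lineno, line in enumerate(block_lines):
            try:
                rec = json.loads(line)
                block = Block(rec["height"], rec["timestamp"],
                              tuple(rec["txids"]), rec["prev_hash"],
                              rec["hash"])
            except (ValueError, KeyError, TypeError):
                ok = False
                bad_heights.append(lineno)
                blocks.append(None)
                continue
            expected = _block_hash(block.height, block.timestamp,
                                   block.txids, block.prev_hash)
            if (block.height != lineno or block.prev_hash != prev_hash
                    or block.hash != expected):
                ok = False
                bad_heights.append(lineno)
            prev_hash = block.hash
            blocks.append(block)

        # ordinal -> block height, via cumulative txid counts (publication
        # order equals mining order in this single-node store)
        txid_height: dict[str, int] = {}
        ordinal_height: list[Optional[int]] = []
        for block in blocks:
            if block is None:
                continue
            for txid in block.txids:
                txid_height[txid] = block.height
                ordinal_height.append(block.height)

        def height_of(ordinal: int, txid: Optional[str]) -> Optional[int]:
            if txid is not None and txid in txid_height:
                return txid_height[txid]
            if ordinal < len(ordinal_height):
                return ordinal_height[ordinal]
            return None  # pending

        for ordinal, line in enumerate(item_lines):
            try:
                rec = json.loads(line)
                expected = _item_txid(rec["stream"], rec["publisher"],
                                      tuple(rec["keys"]),
                                      bytes.fromhex(rec["data"]),
                                      rec["counter"], rec["blocktime"])
                stored = rec["txid"]
            except (ValueError, KeyError, TypeError):
                ok = False
                h = height_of(ordinal, None)
                if h is not None:
                    bad_heights.append(h)
                continue
            if stored != expected:
                ok = False
                h = height_of(ordinal, stored)
                if h is not None:
                    bad_heights.append(h)
            elif stored not in txid_height and ordinal < len(ordinal_height):
                # a mined slot holds a txid no block references
                ok = False
                bad_heights.append(ordinal_height[ordinal])

        if ok:
            return IntegrityReport(True, None)
        return IntegrityReport(False, min(bad_heights) if bad_heights else None)
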