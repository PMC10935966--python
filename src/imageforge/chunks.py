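"""Size-bounded archive volumes with bit-exact reassembly.

Captured files are serialized into **one deterministic tar+gzip stream**
(entries sorted by path, zeroed mtimes, normalized ownership/permissions,
gzip at a fixed level with no embedded timestamp) which is then byte-split
into volumes.  Every volume is exactly ``limit`` bytes except the last, so
the volume count is ``ceil(stream_bytes / limit)``.

The default limit is 24 x 10^6 bytes: strictly below 25 MB under both the
decimal (25 x 10^6) and binary (25 x 2^20) readings of the
repository-hosting bound, so the volumes are uploadable either way.  Byte-splitting one
stream (rather than bin-packing whole files) means single files larger
than the limit are handled naturally.

Reassembly verifies each volume's SHA-256 and the whole-stream digest
before extracting anything; a corrupt or missing volume refuses extraction.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import json
import tarfile
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ForgeError, IntegrityError

#: Volume limit such that every volume is < 25 MB and < 25 MiB.
DEFAULT_VOLUME_LIMIT = 24 * 10**6

_GZIP_LEVEL = 6


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


@dataclass(frozen=True)
class VolumeInfo:
    filename: str
    byte_size: int
    checksum: str


@dataclass(frozen=True)
class EntryIndex:
    """Location of one member's data within the *uncompressed* tar stream."""

    path: str
    offset: int
    length: int


@dataclass
class ChunkSet:
    """Manifest of one chunked archive stream."""

    volumes: list[VolumeInfo]
    total_stream_bytes: int
    volume_limit_bytes: int
    stream_checksum: str
    entry_index: list[EntryIndex] = field(default_factory=list)
    stem: str = "archive"

    def to_dict(self) -> dict:
        return {
            "stem": self.stem,
            "volume_limit_bytes": self.volume_limit_bytes,
            "total_stream_bytes": self.total_stream_bytes,
            "stream_checksum": self.stream_checksum,
            "volumes": [
                {"filename": v.filename, "byte_size": v.byte_size, "checksum": v.checksum}
                for v in self.volumes
            ],
            "entry_index": [
                {"path": e.path, "offset": e.offset, "length": e.length}
                for e in self.entry_index
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "ChunkSet":
        return cls(
            volumes=[VolumeInfo(v["filename"], v["byte_size"], v["checksum"]) for v in d["volumes"]],
            total_stream_bytes=d["total_stream_bytes"],
            volume_limit_bytes=d["volume_limit_bytes"],
            stream_checksum=d["stream_checksum"],
            entry_index=[EntryIndex(e["path"], e["offset"], e["length"]) for e in d["entry_index"]],
            stem=d["stem"],
        )

    @classmethod
    def from_json(cls, text: str) -> "ChunkSet":
        return cls.from_dict(json.loads(text))


def build_stream(files: Sequence[tuple[str, bytes]]) -> tuple[bytes, list[EntryIndex]]:
    """Build the deterministic tar+gzip stream for a file set.

    Entries are sorted by path; tar metadata (mtime, uid/gid, mode, owner
    names) is normalized so identical bytes in produce identical bytes out.
    """
    paths = [p for p, _ in files]
    if len(set(paths)) != len(paths):
        dupes = sorted({p for p in paths if paths.count(p) > 1})
        raise ForgeError(f"duplicate paths in file set: {dupes}")
    by_path = sorted(files, key=lambda pc: pc[0])

    tar_buf = io.BytesIO()
    index: list[EntryIndex] = []
    with tarfile.open(fileobj=tar_buf, mode="w", format=tarfile.USTAR_FORMAT) as tf:
        for path, content in by_path:
            info = tarfile.TarInfo(name=path)
            info.size = len(content)
            info.mtime = 0
            info.uid = info.gid = 0
            info.uname = info.gname = ""
            info.mode = 0o644
            tf.addfile(info, io.BytesIO(content))
            member = tf.getmember(path)
            index.append(EntryIndex(path=path, offset=member.offset_data, length=len(content)))
    raw_tar = tar_buf.getvalue()

    gz_buf = io.BytesIO()
    with gzip.GzipFile(fileobj=gz_buf, mode="wb", compresslevel=_GZIP_LEVEL, mtime=0) as gz:
        gz.write(raw_tar)
    return gz_buf.getvalue(), index


def chunk_files(
    files: Sequence[tuple[str, bytes]],
    limit: int = DEFAULT_VOLUME_LIMIT,
    stem: str = "archive",
) -> tuple[ChunkSet, dict[str, bytes]]:
    """Serialize a file set into volumes of at most ``limit`` bytes.

    Returns the :class:`ChunkSet` manifest and the volume contents keyed by
    volume filename (``<stem>.part0000``, ``<stem>.part0001``, ...).  A
    pure function of ``(files, limit, stem)``.  Zero files yield an empty
    ChunkSet with zero volumes.
    """
    if limit <= 0:
        raise ForgeError(f"volume limit must be positive, got {limit}")
    if not files:
        return (
            ChunkSet(
                volumes=[],
                total_stream_bytes=0,
                volume_limit_bytes=limit,
                stream_checksum=_sha256(b""),
                entry_index=[],
                stem=stem,
            ),
            {},
        )
    stream, index = build_stream(files)
    volumes: list[VolumeInfo] = []
    contents: dict[str, bytes] = {}
    for i in range(0, len(stream), limit):
        part = stream[i : i + limit]
        fname = f"{stem}.part{i // limit:04d}"
        volumes.append(VolumeInfo(filename=fname, byte_size=len(part), checksum=_sha256(part)))
        contents[fname] = part
    chunkset = ChunkSet(
        volumes=volumes,
        total_stream_bytes=len(stream),
        volume_limit_bytes=limit,
        stream_checksum=_sha256(stream),
        entry_index=index,
        stem=stem,
    )
    return chunkset, contents


def reassemble(
    chunkset: ChunkSet, volumes_content: Mapping[str, bytes]
) -> list[tuple[str, bytes]]:
    """Rebuild the original file set from volumes, verifying integrity first.

    Volumes may be supplied in any order (the manifest fixes the order).
    Raises :class:`IntegrityError` naming the missing or corrupt volume;
    nothing is extracted on mismatch.
    """
    parts: list[bytes] = []
    for vol in chunkset.volumes:
        if vol.filename not in volumes_content:
            raise IntegrityError(f"missing volume: {vol.filename}")
        data = volumes_content[vol.filename]
        if len(data) != vol.byte_size or _sha256(data) != vol.checksum:
            raise IntegrityError(f"checksum mismatch in volume: {vol.filename}")
        parts.append(data)
    stream = b"".join(parts)
    if len(stream) != chunkset.total_stream_bytes:
        raise IntegrityError("reassembled stream has wrong length")
    if _sha256(stream) != chunkset.stream_checksum:
        raise IntegrityError("reassembled stream checksum mismatch")
    if not chunkset.volumes:
        return []
    out: list[tuple[str, bytes]] = []
    with tarfile.open(fileobj=io.BytesIO(gzip.decompress(stream)), mode="r:") as tf:
        for member in tf.getmembers():
            fh = tf.extractfile(member)
            out.append((member.name, fh.read() if fh else b""))
    return out
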