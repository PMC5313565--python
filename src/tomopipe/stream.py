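"""Frame streaming: message contract and an in-process PUB/SUB transport.

A scan travels as a header message (shape, counts, angle table), one message
per frame (role, sequence index, raw little-endian payload with an explicit
dtype/shape descriptor) and an end message. The transport is an interface:
this module ships an in-process implementation with the same fan-out
semantics as a network PUB/SUB socket (every subscriber sees every message),
which keeps ingestion testable and bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional

import numpy as np

from .errors import ProtocolError
from .io_formats import RawScan

__all__ = ["StreamMessage", "InProcessTransport", "publish_scan",
           "ingest_stream"]

_ROLES = ("projection", "flat", "dark")


@dataclass
class StreamMessage:
    """One message of the scan stream: header, frame, or end."""

    kind: str  # header | frame | end
    header: Optional[dict] = None
    role: Optional[str] = None
    index: Optional[int] = None
    payload: Optional[bytes] = None
    dtype: Optional[str] = None
    shape: Optional[tuple] = None

    @classmethod
    def frame(cls, role: str, index: int, data: np.ndarray) -> "StreamMessage":
        data = np.ascontiguousarray(data)
        return cls(kind="frame", role=role, index=int(index),
                   payload=data.astype(data.dtype.newbyteorder("<")).tobytes(),
                   dtype=np.dtype(data.dtype).newbyteorder("<").str,
                   shape=tuple(data.shape))

    def decode(self) -> np.ndarray:
        return np.frombuffer(self.payload, dtype=np.dtype(self.dtype)
                             ).reshape(self.shape)


class InProcessTransport:
    """PUB/SUB fan-out over an in-process message list.

    Messages published before or after subscription are all delivered to
    every subscriber in publication order (a late subscriber replays the
    backlog), so any number of subscribers reconstruct identical scans.
    """

    def __init__(self) -> None:
        self._messages: List[StreamMessage] = []

    def publish(self, message: StreamMessage) -> None:
        self._messages.append(message)

    def subscribe(self) -> Iterator[StreamMessage]:
        i = 0
        while i < len(self._messages):
            msg = self._messages[i]
            yield msg
            i += 1
            if msg.kind == "end":
                return


def publish_scan(scan: RawScan, transport: InProcessTransport,
                 order: Optional[List] = None) -> None:
    """Publish a RawScan as a message stream.

    ``order`` optionally permutes the (role, index) frame sequence, to
    exercise out-of-order delivery; the header always goes first and the end
    marker last.
    """
    header = {
        "frame_shape": tuple(scan.frame_shape),
        "n_proj": scan.n_proj,
        "n_flats": scan.flats.shape[0],
        "n_darks": scan.darks.shape[0],
        "angles": [float(a) for a in scan.angles],
        "metadata": dict(scan.metadata),
    }
    transport.publish(StreamMessage(kind="header", header=header))
    sequence = order
    if sequence is None:
        sequence = ([("dark", i) for i in range(scan.darks.shape[0])]
                    + [("flat", i) for i in range(scan.flats.shape[0])]
                    + [("projection", i) for i in range(scan.n_proj)])
    stacks = {"projection": scan.projections, "flat": scan.flats,
              "dark": scan.darks}
    for role, i in sequence:
        transport.publish(StreamMessage.frame(role, i, stacks[role][i]))
    transport.publish(StreamMessage(kind="end"))


def ingest_stream(subscription: Iterator[StreamMessage]) -> RawScan:
    """Accumulate a message stream back into a RawScan.

    Frames are slotted by sequence index per role, so out-of-order delivery
    is re-ordered; a missing header or a duplicate index is a protocol
    error. The result is value-identical to reading the same scan from file.
    """
    header = None
    stacks: Dict[str, Optional[np.ndarray]] = {r: None for r in _ROLES}
    seen: Dict[str, set] = {r: set() for r in _ROLES}
    counts = {}
    for msg in subscription:
        if msg.kind == "header":
            header = msg.header
            counts = {"projection": header["n_proj"],
                      "flat": header["n_flats"],
                      "dark": header["n_darks"]}
        elif msg.kind == "frame":
            if header is None:
                raise ProtocolError("frame received before the stream header")
            role = msg.role
            if role not in _ROLES:
                raise ProtocolError(f"unknown frame role {role!r}")
            if msg.index in seen[role]:
                raise ProtocolError(
                    f"duplicate {role} frame index {msg.index}")
            data = msg.decode()
            if stacks[role] is None:
                stacks[role] = np.zeros((counts[role],) + data.shape,
                                        dtype=data.dtype)
            if not (0 <= msg.index < counts[role]):
                raise ProtocolError(
                    f"{role} frame index {msg.index} outside the announced "
                    f"count {counts[role]}")
            stacks[role][msg.index] = data
            seen[role].add(msg.index)
        elif msg.kind == "end":
            break
        else:
            raise ProtocolError(f"unknown message kind {msg.kind!r}")
    if header is None:
        raise ProtocolError("stream ended without a header")
    for role in _ROLES:
        if len(seen[role]) != counts[role]:
            raise ProtocolError(
                f"incomplete stream: {len(seen[role])}/{counts[role]} "
                f"{role} frames received")
    return RawScan(projections=stacks["projection"], flats=stacks["flat"],
                   darks=stacks["dark"],
                   angles=np.asarray(header["angles"], dtype=float),
                   metadata=dict(header.get("metadata", {})))
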