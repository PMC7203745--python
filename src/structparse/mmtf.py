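"""MMTF v1.0 binary container: msgpack transport plus the field codecs.

Every binary field in an MMTF file is a byte string with a 12-byte header
(big-endian int32 codec id, element count, codec parameter) followed by a
big-endian payload. The fifteen published codecs combine a handful of
primitives: pass-through arrays, fixed-width strings, run-length encoding,
delta encoding, recursive indexing (splitting values too large for the
payload width across consecutive entries) and fixed-point integer
encoding with a divisor parameter.

Both directions are implemented so that decoded arrays can be re-encoded
bit-for-bit, which is what the writer uses.
"""

import struct

import msgpack
import numpy as np


# ---------------------------------------------------------------- primitives

def run_length_decode(values):
    if len(values) % 2:
        raise ValueError("Run-length data needs an even number of integers")
    out = []
    for i in range(0, len(values), 2):
        out.extend([values[i]] * values[i + 1])
    return out


def run_length_encode(values):
    out = []
    for value in values:
        if out and out[-2] == value:
            out[-1] += 1
        else:
            out.extend([value, 1])
    return out


def delta_decode(values):
    return list(np.cumsum(values)) if len(values) else []


def delta_encode(values):
    if not len(values):
        return []
    return [values[0]] + list(np.diff(values))


def recursive_index_decode(values, bits=16):
    limit_hi = 2 ** (bits - 1) - 1
    limit_lo = -(2 ** (bits - 1))
    out = []
    total = 0
    for value in values:
        total += value
        if value != limit_hi and value != limit_lo:
            out.append(total)
            total = 0
    return out


def recursive_index_encode(values, bits=16):
    limit_hi = 2 ** (bits - 1) - 1
    limit_lo = -(2 ** (bits - 1))
    out = []
    for value in values:
        value = int(value)
        # a value at the limit itself still needs a terminating entry
        while value >= limit_hi:
            out.append(limit_hi)
            value -= limit_hi
        while value <= limit_lo:
            out.append(limit_lo)
            value -= limit_lo
        out.append(value)
    return out


def _ints(payload, dtype):
    return np.frombuffer(payload, dtype=dtype).astype(int).tolist()


def _pack_ints(values, dtype):
    return np.asarray(values, dtype=dtype).astype(dtype).tobytes()


# ------------------------------------------------------------------- codecs

def decode_binary_field(field):
    """Decode one MMTF binary field into a plain Python list."""
    if len(field) < 12:
        raise ValueError("Binary field shorter than the 12-byte header")
    codec, length, param = struct.unpack(">iii", field[:12])
    payload = field[12:]
    if codec == 1:
        out = np.frombuffer(payload, dtype=">f4").astype(float).tolist()
    elif codec == 2:
        out = _ints(payload, ">i1")
    elif codec == 3:
        out = _ints(payload, ">i2")
    elif codec == 4:
        out = _ints(payload, ">i4")
    elif codec == 5:
        width = param
        out = [payload[i:i + width].decode("ascii").rstrip("\x00")
               for i in range(0, len(payload), width)]
    elif codec == 6:
        codes = run_length_decode(_ints(payload, ">i4"))
        out = [chr(c) if c else "" for c in codes]
    elif codec == 7:
        out = run_length_decode(_ints(payload, ">i4"))
    elif codec == 8:
        out = [int(v) for v in delta_decode(run_length_decode(_ints(payload, ">i4")))]
    elif codec == 9:
        out = [v / param for v in run_length_decode(_ints(payload, ">i4"))]
    elif codec == 10:
        ints = delta_decode(recursive_index_decode(_ints(payload, ">i2")))
        out = [int(v) / param for v in ints]
    elif codec == 11:
        out = [v / param for v in _ints(payload, ">i2")]
    elif codec == 12:
        out = [v / param for v in recursive_index_decode(_ints(payload, ">i2"))]
    elif codec == 13:
        out = [v / param for v in recursive_index_decode(_ints(payload, ">i1"), bits=8)]
    elif codec == 14:
        out = recursive_index_decode(_ints(payload, ">i2"))
    elif codec == 15:
        out = recursive_index_decode(_ints(payload, ">i1"), bits=8)
    else:
        raise ValueError(f"Unknown MMTF codec id {codec}")
    if len(out) != length:
        raise ValueError(f"Codec {codec}: decoded {len(out)} elements, "
                         f"header promised {length}")
    return out


def encode_binary_field(codec, values, param=0):
    """Encode a list of values as an MMTF binary field under ``codec``."""
    values = list(values)
    header = struct.pack(">iii", codec, len(values), param)
    if codec == 1:
        payload = np.asarray(values, dtype=">f4").tobytes()
    elif codec == 2:
        payload = _pack_ints(values, ">i1")
    elif codec == 3:
        payload = _pack_ints(values, ">i2")
    elif codec == 4:
        payload = _pack_ints(values, ">i4")
    elif codec == 5:
        payload = b"".join(v.encode("ascii").ljust(param, b"\x00") for v in values)
    elif codec == 6:
        codes = [ord(v) if v else 0 for v in values]
        payload = _pack_ints(run_length_encode(codes), ">i4")
    elif codec == 7:
        payload = _pack_ints(run_length_encode(values), ">i4")
    elif codec == 8:
        payload = _pack_ints(run_length_encode(delta_encode(values)), ">i4")
    elif codec == 9:
        ints = [int(round(v * param)) for v in values]
        payload = _pack_ints(run_length_encode(ints), ">i4")
    elif codec == 10:
        ints = [int(round(v * param)) for v in values]
        payload = _pack_ints(recursive_index_encode(delta_encode(ints)), ">i2")
    elif codec == 11:
        payload = _pack_ints([int(round(v * param)) for v in values], ">i2")
    elif codec == 12:
        ints = [int(round(v * param)) for v in values]
        payload = _pack_ints(recursive_index_encode(ints), ">i2")
    elif codec == 13:
        ints = [int(round(v * param)) for v in values]
        payload = _pack_ints(recursive_index_encode(ints, bits=8), ">i1")
    elif codec == 14:
        payload = _pack_ints(recursive_index_encode(values), ">i2")
    elif codec == 15:
        payload = _pack_ints(recursive_index_encode(values, bits=8), ">i1")
    else:
        raise ValueError(f"Unknown MMTF codec id {codec}")
    return header + payload


def _decode_values(obj):
    if isinstance(obj, bytes):
        return decode_binary_field(obj)
    if isinstance(obj, dict):
        return {key: _decode_values(value) for key, value in obj.items()}
    if isinstance(obj, list):
        return [_decode_values(value) for value in obj]
    return obj


def decode_mmtf(content):
    """Unpack an MMTF bytestring into its top-level field mapping, with
    every binary field decoded to plain numeric/string lists."""
    fields = msgpack.unpackb(content, raw=False, strict_map_key=False)
    if not isinstance(fields, dict):
        raise ValueError("MMTF content is not a msgpack map")
    return _decode_values(fields)


def pack_mmtf(fields):
    """msgpack-serialize a top-level field mapping (values already encoded
    where binary encoding is wanted)."""
    return msgpack.packb(fields, use_bin_type=True)
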