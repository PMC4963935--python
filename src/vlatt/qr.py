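"""QR Code model 2 encoder/decoder (byte mode, error-correction level M).

Self-contained symbol codec used for the genome barcode signatures:
Reed-Solomon over GF(256) (polynomial 0x11D), standard function patterns,
mask selection by the four penalty rules, and a decoder that reverses the
whole path (format read, unmasking, zigzag codeword extraction,
de-interleaving, RS error correction, byte-mode parsing).  Versions 1-20
are supported, far beyond the barcode payloads this package emits.
"""

from __future__ import annotations

import numpy as np

# --------------------------------------------------------------------------
# GF(256) arithmetic and Reed-Solomon
# --------------------------------------------------------------------------

_EXP = np.zeros(512, dtype=np.int64)
_LOG = np.zeros(256, dtype=np.int64)


def _init_tables() -> None:
    x = 1
    for i in range(255):
        _EXP[i] = x
        _LOG[x] = i
        x <<= 1
        if x & 0x100:
            x ^= 0x11D
    for i in range(255, 512):
        _EXP[i] = _EXP[i - 255]


_init_tables()


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_EXP[_LOG[a] + _LOG[b]])


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            out[i + j] ^= _gf_mul(a, b)
    return out


def _rs_generator(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, int(_EXP[i])])
    return g


def rs_encode(data: list[int], nsym: int) -> list[int]:
    """Append ``nsym`` Reed-Solomon parity bytes to ``data``."""
    gen = _rs_generator(nsym)
    rem = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], coef)
    return list(data) + rem[len(data):]


def _poly_eval(p: list[int], x: int) -> int:
    y = 0
    for c in p:
        y = _gf_mul(y, x) ^ c
    return y


def _gf_inv(a: int) -> int:
    return int(_EXP[255 - _LOG[a]])


def _gf_pow(a: int, p: int) -> int:
    return int(_EXP[(_LOG[a] * p) % 255])


def rs_decode(codeword: list[int], nsym: int) -> list[int]:
    """Correct up to nsym//2 byte errors; returns the data part.

    Berlekamp-Massey locator, Chien search, Forney magnitudes.  Raises
    ValueError when the word is uncorrectable.
    """
    n = len(codeword)
    synd = [_poly_eval(codeword, int(_EXP[i])) for i in range(nsym)]
    if max(synd) == 0:
        return codeword[:-nsym]

    # Berlekamp-Massey (polynomials stored highest-degree first)
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym):
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= _gf_mul(err_loc[-(j + 1)], synd[i - j])
        old_loc = old_loc + [0]
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = [_gf_mul(c, delta) for c in old_loc]
                old_loc = [_gf_mul(c, _gf_inv(delta)) for c in err_loc]
                err_loc = new_loc
            scaled = [_gf_mul(c, delta) for c in old_loc]
            width = max(len(scaled), len(err_loc))
            a = [0] * (width - len(err_loc)) + err_loc
            b = [0] * (width - len(scaled)) + scaled
            err_loc = [x ^ y for x, y in zip(a, b)]
    while err_loc and err_loc[0] == 0:
        err_loc = err_loc[1:]
    errs = len(err_loc) - 1
    if errs * 2 > nsym:
        raise ValueError("too many errors to correct")

    # Chien search on the reversed locator: a root at x = 2^i marks an
    # error at codeword position n-1-i
    err_loc_rev = list(reversed(err_loc))
    err_pos = []
    for i in range(n):
        if _poly_eval(err_loc_rev, int(_EXP[i])) == 0:
            err_pos.append(n - 1 - i)
    if len(err_pos) != errs:
        raise ValueError("error locator failure")

    # Forney, using the normalized errata locator rebuilt from positions
    coef_pos = [n - 1 - p for p in err_pos]
    X = [_gf_pow(2, cp) for cp in coef_pos]
    errata_loc = [1]
    for Xi in X:
        errata_loc = _poly_mul(errata_loc, [Xi, 1])
    synd_rev = list(reversed(synd))
    prod = _poly_mul(synd_rev, errata_loc)
    # omega = prod mod x^(errs+1): keep the lowest errs+1 coefficients
    err_eval = prod[len(prod) - (errs + 1):]
    out = list(codeword)
    for i, Xi in enumerate(X):
        Xi_inv = _gf_inv(Xi)
        loc_prime = 1
        for j, Xj in enumerate(X):
            if j != i:
                loc_prime = _gf_mul(loc_prime, 1 ^ _gf_mul(Xi_inv, Xj))
        if loc_prime == 0:
            raise ValueError("Forney failure")
        # b=0 syndromes: e_k = Omega(X_k^-1) / prod_{j!=k}(1 - X_j X_k^-1)
        y = _poly_eval(err_eval, Xi_inv)
        magnitude = _gf_mul(y, _gf_inv(loc_prime))
        out[err_pos[i]] ^= magnitude

    synd2 = [_poly_eval(out, int(_EXP[i])) for i in range(nsym)]
    if max(synd2) != 0:
        raise ValueError("residual errors after correction")
    return out[:-nsym]


# --------------------------------------------------------------------------
# Version tables (error-correction level M only)
# --------------------------------------------------------------------------

# version -> (ec codewords per block, [data codewords per block, ...])
_BLOCKS_M = {
    1: (10, [16]),
    2: (16, [28]),
    3: (26, [44]),
    4: (18, [32, 32]),
    5: (24, [43, 43]),
    6: (16, [27] * 4),
    7: (18, [31] * 4),
    8: (22, [38, 38, 39, 39]),
    9: (22, [36, 36, 36, 37, 37]),
    10: (26, [43, 43, 43, 43, 44]),
    11: (30, [50] + [51] * 4),
    12: (22, [36] * 6 + [37] * 2),
    13: (22, [37] * 8 + [38]),
    14: (24, [40] * 4 + [41] * 5),
    15: (24, [41] * 5 + [42] * 5),
    16: (28, [45] * 7 + [46] * 3),
    17: (28, [46] * 10 + [47]),
    18: (26, [43] * 9 + [44] * 4),
    19: (26, [44] * 3 + [45] * 11),
    20: (26, [41] * 3 + [42] * 13),
}

_ALIGN = {
    1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30], 6: [6, 34],
    7: [6, 22, 38], 8: [6, 24, 42], 9: [6, 26, 46], 10: [6, 28, 50],
    11: [6, 30, 54], 12: [6, 32, 58], 13: [6, 34, 62], 14: [6, 26, 46, 66],
    15: [6, 26, 48, 70], 16: [6, 26, 50, 74], 17: [6, 30, 54, 78],
    18: [6, 30, 56, 82], 19: [6, 30, 58, 86], 20: [6, 34, 62, 90],
}

MAX_VERSION = max(_BLOCKS_M)


def _data_capacity(version: int) -> int:
    ec, blocks = _BLOCKS_M[version]
    return sum(blocks)


def _payload_capacity(version: int) -> int:
    header = 2 if version <= 9 else 3  # mode nibble + count + terminator fit
    return _data_capacity(version) - header


def max_payload_bytes() -> int:
    return _payload_capacity(MAX_VERSION)


def _size(version: int) -> int:
    return 17 + 4 * version


# --------------------------------------------------------------------------
# Matrix construction
# --------------------------------------------------------------------------


def _function_mask(version: int) -> np.ndarray:
    """Boolean map of modules reserved for function patterns/format."""
    n = _size(version)
    f = np.zeros((n, n), dtype=bool)
    for r, c in ((0, 0), (0, n - 7), (n - 7, 0)):
        f[max(0, r - 1): r + 8, max(0, c - 1): c + 8] = True
    f[6, :] = True
    f[:, 6] = True
    for r in _ALIGN[version]:
        for c in _ALIGN[version]:
            if f[r, c]:
                # skip alignment patterns overlapping finders
                if (r < 9 and c < 9) or (r < 9 and c > n - 10) or (
                    r > n - 10 and c < 9
                ):
                    continue
            f[r - 2: r + 3, c - 2: c + 3] = True
    # format info areas
    f[8, 0:9] = True
    f[0:9, 8] = True
    f[8, n - 8:] = True
    f[n - 8:, 8] = True
    if version >= 7:
        f[n - 11: n - 8, 0:6] = True
        f[0:6, n - 11: n - 8] = True
    return f


def _place_function_patterns(m: np.ndarray, version: int) -> None:
    n = m.shape[0]

    def finder(r, c):
        m[r: r + 7, c: c + 7] = True
        m[r + 1: r + 6, c + 1: c + 6] = False
        m[r + 2: r + 5, c + 2: c + 5] = True

    finder(0, 0)
    finder(0, n - 7)
    finder(n - 7, 0)
    for i in range(8, n - 8):
        m[6, i] = i % 2 == 0
        m[i, 6] = i % 2 == 0
    for r in _ALIGN[version]:
        for c in _ALIGN[version]:
            if (r < 9 and c < 9) or (r < 9 and c > n - 10) or (
                r > n - 10 and c < 9
            ):
                continue
            m[r - 2: r + 3, c - 2: c + 3] = True
            m[r - 1: r + 2, c - 1: c + 2] = False
            m[r, c] = True
    m[n - 8, 8] = True  # dark module


_FORMAT_GEN = 0b10100110111
_FORMAT_MASK = 0b101010000010010
_EC_M_BITS = 0b00


def _bch15_5(value5: int) -> int:
    v = value5 << 10
    rem = v
    for i in range(14, 9, -1):
        if rem & (1 << i):
            rem ^= _FORMAT_GEN << (i - 10)
    return (v | rem) ^ _FORMAT_MASK


def _format_bits(mask_id: int) -> list[int]:
    word = _bch15_5((_EC_M_BITS << 3) | mask_id)
    return [(word >> (14 - i)) & 1 for i in range(15)]  # b14 first


def _place_format(m: np.ndarray, mask_id: int) -> None:
    n = m.shape[0]
    bits = _format_bits(mask_id)  # bits[0] = b14 ... bits[14] = b0
    coords1 = [
        (8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
        (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8),
    ]
    coords2 = [(n - 1 - i, 8) for i in range(7)] + [
        (8, n - 8 + i) for i in range(8)
    ]
    for (r, c), b in zip(coords1, bits):
        m[r, c] = bool(b)
    for (r, c), b in zip(coords2, bits):
        m[r, c] = bool(b)


_VERSION_GEN = 0x1F25


def _version_bits(version: int) -> int:
    v = version << 12
    rem = v
    for i in range(17, 11, -1):
        if rem & (1 << i):
            rem ^= _VERSION_GEN << (i - 12)
    return v | rem


def _place_version(m: np.ndarray, version: int) -> None:
    if version < 7:
        return
    n = m.shape[0]
    bits = _version_bits(version)
    for k in range(18):
        b = bool((bits >> k) & 1)
        m[n - 11 + k % 3, k // 3] = b
        m[k // 3, n - 11 + k % 3] = b


def _zigzag_coords(version: int) -> list[tuple[int, int]]:
    n = _size(version)
    func = _function_mask(version)
    coords = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for r in rows:
            for c in (col, col - 1):
                if not func[r, c]:
                    coords.append((r, c))
        upward = not upward
        col -= 2
    return coords


def _mask_fn(mask_id: int):
    return [
        lambda i, j: (i + j) % 2 == 0,
        lambda i, j: i % 2 == 0,
        lambda i, j: j % 3 == 0,
        lambda i, j: (i + j) % 3 == 0,
        lambda i, j: (i // 2 + j // 3) % 2 == 0,
        lambda i, j: (i * j) % 2 + (i * j) % 3 == 0,
        lambda i, j: ((i * j) % 2 + (i * j) % 3) % 2 == 0,
        lambda i, j: ((i + j) % 2 + (i * j) % 3) % 2 == 0,
    ][mask_id]


def _penalty(m: np.ndarray) -> int:
    n = m.shape[0]
    score = 0
    # N1: runs >= 5 in rows and columns
    for grid in (m, m.T):
        for row in grid:
            run = 1
            for i in range(1, n):
                if row[i] == row[i - 1]:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + run - 5
                    run = 1
            if run >= 5:
                score += 3 + run - 5
    # N2: 2x2 blocks
    blocks = (
        (m[:-1, :-1] == m[1:, :-1])
        & (m[:-1, :-1] == m[:-1, 1:])
        & (m[:-1, :-1] == m[1:, 1:])
    )
    score += 3 * int(blocks.sum())
    # N3: finder-like patterns
    pat1 = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
    pat2 = pat1[::-1]
    for grid in (m, m.T):
        for row in grid:
            for i in range(n - 10):
                w = row[i: i + 11]
                if np.array_equal(w, pat1) or np.array_equal(w, pat2):
                    score += 40
    # N4: dark proportion
    dark = m.sum() / m.size * 100
    score += 10 * int(abs(dark - 50) // 5)
    return int(score)


# --------------------------------------------------------------------------
# Encode / decode
# --------------------------------------------------------------------------


def _build_codewords(payload: bytes, version: int) -> list[int]:
    cap = _data_capacity(version)
    bits: list[int] = []

    def push(value: int, width: int) -> None:
        for i in range(width - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)  # byte mode
    push(len(payload), 8 if version <= 9 else 16)
    for byte in payload:
        push(byte, 8)
    # terminator and byte alignment
    bits.extend([0] * min(4, cap * 8 - len(bits)))
    while len(bits) % 8:
        bits.append(0)
    data = [
        int("".join(map(str, bits[i: i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    pad = [0xEC, 0x11]
    i = 0
    while len(data) < cap:
        data.append(pad[i % 2])
        i += 1
    return data


def _interleave(data: list[int], version: int) -> list[int]:
    ec_len, block_sizes = _BLOCKS_M[version]
    blocks = []
    pos = 0
    for size in block_sizes:
        blocks.append(data[pos: pos + size])
        pos += size
    ec_blocks = [rs_encode(b, ec_len)[len(b):] for b in blocks]
    out = []
    for i in range(max(block_sizes)):
        for b in blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(ec_len):
        for e in ec_blocks:
            out.append(e[i])
    return out


def _deinterleave(codewords: list[int], version: int) -> list[int]:
    ec_len, block_sizes = _BLOCKS_M[version]
    nblocks = len(block_sizes)
    blocks: list[list[int]] = [[] for _ in range(nblocks)]
    idx = 0
    for i in range(max(block_sizes)):
        for b in range(nblocks):
            if i < block_sizes[b]:
                blocks[b].append(codewords[idx])
                idx += 1
    ecs: list[list[int]] = [[] for _ in range(nblocks)]
    for i in range(ec_len):
        for b in range(nblocks):
            ecs[b].append(codewords[idx])
            idx += 1
    data = []
    for b in range(nblocks):
        data.extend(rs_decode(blocks[b] + ecs[b], ec_len))
    return data


def encode(text: str) -> np.ndarray:
    """Encode text as a QR module matrix (True = dark), EC level M.

    The smallest version fitting the payload is used; payloads beyond the
    version-20 capacity raise a ValueError naming the maximum length.
    """
    payload = text.encode("utf-8")
    version = None
    for v in range(1, MAX_VERSION + 1):
        if len(payload) <= _payload_capacity(v):
            version = v
            break
    if version is None:
        raise ValueError(
            f"payload of {len(payload)} bytes exceeds the maximum of "
            f"{max_payload_bytes()} bytes (version {MAX_VERSION}, level M)"
        )
    n = _size(version)
    codewords = _interleave(_build_codewords(payload, version), version)
    coords = _zigzag_coords(version)

    base = np.zeros((n, n), dtype=bool)
    _place_function_patterns(base, version)
    _place_version(base, version)

    bitstream = []
    for cw in codewords:
        for i in range(7, -1, -1):
            bitstream.append((cw >> i) & 1)
    bitstream.extend([0] * (len(coords) - len(bitstream)))

    best = None
    for mask_id in range(8):
        m = base.copy()
        fn = _mask_fn(mask_id)
        for (r, c), b in zip(coords, bitstream):
            m[r, c] = bool(b) ^ fn(r, c)
        _place_format(m, mask_id)
        p = _penalty(m)
        if best is None or p < best[0]:
            best = (p, m)
    return best[1]


def _read_format(m: np.ndarray) -> int:
    """Recover the mask id from the format information (EC level M)."""
    coords1 = [
        (8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
        (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8),
    ]
    read = 0
    for r, c in coords1:
        read = (read << 1) | int(m[r, c])
    best = None
    for ec in range(4):
        for mask_id in range(8):
            word = _bch15_5((ec << 3) | mask_id)
            dist = bin(word ^ read).count("1")
            if best is None or dist < best[0]:
                best = (dist, ec, mask_id)
    dist, ec, mask_id = best
    if dist > 3:
        raise ValueError("unreadable format information")
    if ec != _EC_M_BITS:
        raise ValueError("only EC level M symbols are produced/decoded here")
    return mask_id


def decode(matrix: np.ndarray) -> str:
    """Decode a (clean or lightly damaged) module matrix back to text."""
    m = np.asarray(matrix, dtype=bool)
    n = m.shape[0]
    if m.shape != (n, n) or (n - 17) % 4:
        raise ValueError("not a QR module matrix")
    version = (n - 17) // 4
    if version not in _BLOCKS_M:
        raise ValueError(f"unsupported version {version}")
    mask_id = _read_format(m)
    fn = _mask_fn(mask_id)
    coords = _zigzag_coords(version)
    bits = [int(m[r, c]) ^ int(fn(r, c)) for r, c in coords]
    ncw = sum(_BLOCKS_M[version][1]) + _BLOCKS_M[version][0] * len(
        _BLOCKS_M[version][1]
    )
    codewords = [
        int("".join(map(str, bits[i: i + 8])), 2)
        for i in range(0, ncw * 8, 8)
    ]
    data = _deinterleave(codewords, version)
    # parse byte mode
    stream = 0
    for b in data:
        stream = (stream << 8) | b
    total_bits = len(data) * 8

    def take(pos, width):
        shift = total_bits - pos - width
        return (stream >> shift) & ((1 << width) - 1), pos + width

    mode, pos = take(0, 4)
    if mode != 0b0100:
        raise ValueError(f"unsupported mode {mode:04b}")
    cw, pos = take(pos, 8 if version <= 9 else 16)
    out = bytearray()
    for _ in range(cw):
        byte, pos = take(pos, 8)
        out.append(byte)
    return out.decode("utf-8")


def save_png(matrix: np.ndarray, path, scale: int = 8, border: int = 4) -> None:
    """Write the symbol as a PNG with a quiet zone."""
    from PIL import Image

    m = np.asarray(matrix, dtype=bool)
    n = m.shape[0]
    canvas = np.ones((n + 2 * border, n + 2 * border), dtype=np.uint8) * 255
    canvas[border: border + n, border: border + n] = np.where(m, 0, 255)
    img = Image.fromarray(canvas, mode="L").resize(
        ((n + 2 * border) * scale, (n + 2 * border) * scale), Image.NEAREST
    )
    img.save(path)
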