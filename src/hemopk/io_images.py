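"""Reading and writing two-channel image fields (TIFF or PNG).

A field is stored as two files sharing a stem: ``<stem>_dapi.<ext>``
(nuclear stain) and ``<stem>_green.<ext>`` (probe channel).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .imaging import ImagePair

_EXTS = (".tif", ".tiff", ".png")


def _read(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    from PIL import Image

    return np.asarray(Image.open(path).convert("I"), dtype=float)


def _write(path: Path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr.astype(np.int32), mode="I").save(path)


def read_image_pairs(directory) -> list[tuple[str, ImagePair]]:
    """All (stem, ImagePair) found in a directory, sorted by stem."""
    directory = Path(directory)
    pairs = []
    for dapi in sorted(directory.iterdir()):
        if dapi.suffix.lower() not in _EXTS or not dapi.stem.endswith("_dapi"):
            continue
        stem = dapi.stem[: -len("_dapi")]
        green = next((directory / f"{stem}_green{ext}" for ext in _EXTS
                      if (directory / f"{stem}_green{ext}").exists()), None)
        if green is None:
            continue
        pairs.append((stem, ImagePair(_read(dapi), _read(green))))
    return pairs


def write_image_pair(directory, stem: str, pair: ImagePair,
                     ext: str = ".tif") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write(directory / f"{stem}_dapi{ext}", pair.nuclear_channel)
    _write(directory / f"{stem}_green{ext}", pair.green_channel)
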