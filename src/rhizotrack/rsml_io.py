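"""Root System Markup Language (RSML) reading and writing.

The 2D+t model is serialized as standard RSML 1.0 — scene, plants, nested
roots with polyline geometry — with two polyline-domain functions per root:
``time`` (continuous observation index of each node) and ``extrapolated``
(0/1 per node).  Coordinates are stored raw in pixels; the µm/px resolution
and the timestep in hours live in the metadata, so physical conversion stays
the concern of the phene extraction.  Output is deterministic: plants are
ordered by seed position left to right and laterals by attachment position
from root to tip, and floats are printed with a fixed format — two writes of
the same model are byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from lxml import etree

from .model import Organ, Plant, RootSystemModel

__all__ = ["RsmlError", "write_rsml", "read_rsml"]

SOFTWARE_TAG = "rhizotrack"
_F = "{:.6f}"


class RsmlError(ValueError):
    pass


def _fmt(x: float) -> str:
    return _F.format(float(x))


def write_rsml(model: RootSystemModel, path: str | Path) -> Path:
    """Write the model to an RSML file; returns the path written."""
    model.validate()
    root = etree.Element("rsml", version="1.0")
    meta = etree.SubElement(root, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "pixel"
    etree.SubElement(meta, "resolution").text = _fmt(model.px_size_um)
    etree.SubElement(meta, "last-modified").text = "-"
    etree.SubElement(meta, "software").text = SOFTWARE_TAG
    props = etree.SubElement(meta, "property-definitions")
    for name, unit in (("timestep", "hour"), ("observations", "count")):
        pd = etree.SubElement(props, "property-definition")
        etree.SubElement(pd, "label").text = name
        etree.SubElement(pd, "type").text = "float"
        etree.SubElement(pd, "unit").text = unit
    mprops = etree.SubElement(meta, "properties")
    etree.SubElement(mprops, "property", label="timestep",
                     value=_fmt(model.timestep_h))
    etree.SubElement(mprops, "property", label="observations",
                     value=str(int(model.n_timesteps)))

    scene = etree.SubElement(root, "scene")
    order = np.argsort([p.seed_xy[0] for p in model.plants], kind="stable")
    for rank, ip in enumerate(order):
        plant = model.plants[ip]
        pel = etree.SubElement(scene, "plant", id=str(rank + 1),
                               label=f"plant_{rank + 1}")
        primary = plant.primary
        if primary is None:
            continue
        rel = _write_root(pel, primary, f"{rank + 1}")
        laterals = [(o.attachment_index if o.attachment_index is not None
                     else 10 ** 9, k, o)
                    for k, o in enumerate(plant.organs) if o.order == 2]
        laterals.sort(key=lambda t: (t[0], t[1]))
        for j, (_, _, lat) in enumerate(laterals):
            _write_root(rel, lat, f"{rank + 1}.{j + 1}")
    tree = etree.ElementTree(root)
    path = Path(path)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")
    return path


def _write_root(parent_el, organ: Organ, rid: str):
    rel = etree.SubElement(parent_el, "root", id=rid,
                           label=organ.label or f"root_{rid}")
    geom = etree.SubElement(rel, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for x, y, _t in organ.points:
        etree.SubElement(poly, "point", x=_fmt(x), y=_fmt(y))
    fns = etree.SubElement(rel, "functions")
    fn_t = etree.SubElement(fns, "function", name="time", domain="polyline")
    for _x, _y, t in organ.points:
        etree.SubElement(fn_t, "sample", value=_fmt(t))
    fn_e = etree.SubElement(fns, "function", name="extrapolated",
                            domain="polyline")
    for flag in organ.extrapolated:
        etree.SubElement(fn_e, "sample", value=str(int(flag)))
    return rel


def read_rsml(path: str | Path) -> RootSystemModel:
    """Parse an RSML file into a RootSystemModel.

    Reads both this writer's dialect and plain time-free RSML: when a root
    has no ``time`` function all its nodes get the last observation index,
    with a warning.  Malformed geometry or function sample counts raise
    :class:`RsmlError` naming the offending element.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise RsmlError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    meta = root.find("metadata")
    px_size_um = 1.0
    timestep_h = 1.0
    n_timesteps = 1
    if meta is not None:
        res = meta.findtext("resolution")
        if res:
            px_size_um = float(res)
        for prop in meta.iter("property"):
            if prop.get("label") == "timestep":
                timestep_h = float(prop.get("value"))
            elif prop.get("label") == "observations":
                n_timesteps = int(float(prop.get("value")))
    scene = root.find("scene")
    if scene is None:
        raise RsmlError("missing <scene> element")
    plants = []
    warned = False
    for pel in scene.findall("plant"):
        plant = Plant([])
        for rel in pel.findall("root"):
            primary, warned = _read_root(rel, n_timesteps, warned)
            plant.organs.append(primary)
            primary_index = len(plant.organs) - 1
            for sub in rel.findall("root"):
                lat, warned = _read_root(sub, n_timesteps, warned)
                lat.order = 2
                lat.parent = primary_index
                base = lat.points[0, :2]
                lat.attachment_index = int(np.argmin(np.linalg.norm(
                    primary.points[:, :2] - base, axis=1)))
                plant.organs.append(lat)
        prim = plant.primary
        if prim is not None:
            plant.seed_xy = (float(prim.points[0, 0]),
                             float(prim.points[0, 1]))
        plants.append(plant)
    model = RootSystemModel(plants, px_size_um, timestep_h, n_timesteps)
    model.validate()
    return model


def _read_root(rel, n_timesteps: int, warned: bool):
    rid = rel.get("id", "?")
    poly = rel.find("geometry/polyline")
    if poly is None:
        raise RsmlError(f"root {rid}: missing geometry/polyline")
    pts = [(float(p.get("x")), float(p.get("y")))
           for p in poly.findall("point")]
    if len(pts) < 2:
        raise RsmlError(f"root {rid}: fewer than 2 points")
    n = len(pts)
    times = None
    flags = None
    for fn in rel.findall("functions/function"):
        samples = [float(s.get("value")) for s in fn.findall("sample")]
        if len(samples) != n:
            raise RsmlError(
                f"root {rid}: function '{fn.get('name')}' has "
                f"{len(samples)} samples for {n} points")
        if fn.get("name") == "time":
            times = samples
        elif fn.get("name") == "extrapolated":
            flags = [bool(int(s)) for s in samples]
    if times is None:
        if not warned:
            warnings.warn("RSML carries no 'time' function; assigning all "
                          "nodes the last observation index", stacklevel=3)
            warned = True
        times = [float(n_timesteps)] * n
    organ = Organ(np.column_stack([np.asarray(pts), times]),
                  order=1,
                  extrapolated=np.asarray(flags) if flags is not None else None,
                  label=rel.get("label", ""))
    return organ, warned
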