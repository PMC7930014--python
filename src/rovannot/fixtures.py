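"""Materialise a complete miniature synthetic study on disk.

Two 200-second virtual movies (20 ten-second clips each, 25 fps), eight
annotators at 0.9 sensitivity/specificity, rectangle annotations on the
planned frames, one noisy detector stream, and a square footage map — every
file in the exact CSV schema its consuming pipeline stage expects.  Used by
the ``make-fixtures`` CLI command and by the end-to-end tests.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import db, synthetic
from .yolo import write_detections

N_MOVIES = 2
N_ANNOTATORS = 8
MOVIE_DURATION_S = 200.0
FPS = 25.0


def build_scenes(seed: int) -> list[synthetic.TrueScene]:
    return [
        synthetic.make_scene(
            f"movie{m:02d}", seed=seed * 1000 + m, n_tracks=4,
            fps=FPS, duration_s=MOVIE_DURATION_S,
        )
        for m in range(N_MOVIES)
    ]


def materialize_study(out_dir: Path, seed: int = 0) -> dict[str, Path]:
    """Write the miniature study's input files; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenes = build_scenes(seed)
    profiles = synthetic.default_profiles(N_ANNOTATORS)
    paths: dict[str, Path] = {}

    movies_rows = []
    clip_rows = []
    clip_ann_rows = []
    frame_ann_rows = []
    detections = []
    square_rows = []
    for i, scene in enumerate(scenes):
        movies_rows.append((scene.movie_id, f"site{i:02d}", scene.fps, scene.duration_s))
        for t in synthetic.clip_truths(scene):
            clip_rows.append((t.clip.movie_id, t.clip.clip_index,
                              t.clip.start_s, t.clip.end_s))
        for a in synthetic.simulate_clip_annotations(scene, profiles, seed + 17 + i):
            clip_ann_rows.append((a.subject_id, a.annotator_id, a.choice_id,
                                  a.individual_count, a.first_seen_s))
        for fa in synthetic.simulate_frame_annotations(scene, profiles, seed + 41 + i):
            if fa.boxes:
                for b in fa.boxes:
                    frame_ann_rows.append((fa.subject_id, fa.annotator_id,
                                           b.x, b.y, b.w, b.h))
            else:
                frame_ann_rows.append((fa.subject_id, fa.annotator_id,
                                       None, None, None, None))
        detections.extend(
            synthetic.simulate_detections(scene, 0.8, 0.1, 0.01, seed + 59 + i)
        )
        # four equal footage spans (grid squares) per movie
        n_frames = scene.n_frames
        for q in range(4):
            square_rows.append((f"sq{i}{q}", scene.movie_id,
                                q * n_frames // 4, (q + 1) * n_frames // 4 - 1))

    paths["movies"] = out_dir / "movies.csv"
    pd.DataFrame(movies_rows, columns=["movie_id", "site_id", "fps", "duration_s"]
                 ).to_csv(paths["movies"], index=False)
    paths["sites"] = out_dir / "sites.csv"
    pd.DataFrame(
        [(f"site{i:02d}", f"Synthetic site {i}", 58.87 + 0.01 * i, 11.09 + 0.01 * i)
         for i in range(N_MOVIES)],
        columns=["site_id", "name", "decimal_latitude", "decimal_longitude"],
    ).to_csv(paths["sites"], index=False)
    paths["clips"] = out_dir / "clips.csv"
    pd.DataFrame(clip_rows, columns=["movie_id", "clip_index", "start_s", "end_s"]
                 ).to_csv(paths["clips"], index=False)
    paths["clip_annotations"] = out_dir / "clip_annotations.csv"
    pd.DataFrame(clip_ann_rows, columns=["subject_id", "annotator_id", "choice_id",
                                         "individual_count", "first_seen_s"]
                 ).to_csv(paths["clip_annotations"], index=False)
    paths["frame_annotations"] = out_dir / "frame_annotations.csv"
    pd.DataFrame(frame_ann_rows, columns=["subject_id", "annotator_id",
                                          "x", "y", "w", "h"]
                 ).to_csv(paths["frame_annotations"], index=False)
    paths["detections"] = out_dir / "detections.csv"
    write_detections(detections, paths["detections"])
    paths["square_map"] = out_dir / "square_map.csv"
    pd.DataFrame(square_rows, columns=["square_id", "movie_id",
                                       "frame_no_start", "frame_no_end"]
                 ).to_csv(paths["square_map"], index=False)

    conn = db.create_schema(out_dir / "study.db")
    db.insert_sites(conn, [db.Site(f"site{i:02d}", f"Synthetic site {i}",
                                   58.87 + 0.01 * i, 11.09 + 0.01 * i)
                           for i in range(N_MOVIES)])
    db.insert_movies(conn, [db.Movie(m, s, f, d)
                            for m, s, f, d in movies_rows])
    conn.close()
    paths["db"] = out_dir / "study.db"
    return paths
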