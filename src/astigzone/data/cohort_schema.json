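{
  "format": "CSV (RFC-4180, UTF-8, '.' decimal separator), one row per eye",
  "axis_convention": "degrees, [0, 180), axis 180 canonicalised to 0",
  "cylinder_convention": "minus by default; declare plus-cylinder input via the reader dialect",
  "columns": [
    {"name": "patient_id", "type": "string", "required": true, "description": "Opaque patient identifier; two eyes of one patient share it"},
    {"name": "eye_id", "type": "string", "required": true, "description": "Opaque unique eye identifier"},
    {"name": "laterality", "type": "string", "required": true, "description": "OD (right) or OS (left)"},
    {"name": "age", "type": "float", "required": true, "units": "years", "description": "Age at surgery, in (0, 120)"},
    {"name": "sex", "type": "string", "required": true, "description": "M or F"},
    {"name": "axial_length", "type": "float", "required": true, "units": "mm", "description": "Optical-biometry axial length, in (15, 40)"},
    {"name": "iol_power", "type": "float", "required": true, "units": "D", "description": "Implanted (nontoric) IOL spherical power"},
    {"name": "preop_flat_k_24", "type": "float", "required": false, "units": "D", "description": "Preoperative flattest keratometry, 2.4-mm zone"},
    {"name": "preop_steep_k_24", "type": "float", "required": false, "units": "D", "description": "Preoperative steepest keratometry, 2.4-mm zone"},
    {"name": "preop_steep_axis_24", "type": "float", "required": false, "units": "deg", "description": "Preoperative steep-meridian axis, 2.4-mm zone"},
    {"name": "preop_flat_k_33", "type": "float", "required": false, "units": "D", "description": "Preoperative flattest keratometry, 3.3-mm zone"},
    {"name": "preop_steep_k_33", "type": "float", "required": false, "units": "D", "description": "Preoperative steepest keratometry, 3.3-mm zone"},
    {"name": "preop_steep_axis_33", "type": "float", "required": false, "units": "deg", "description": "Preoperative steep-meridian axis, 3.3-mm zone"},
    {"name": "postop_flat_k_24", "type": "float", "required": false, "units": "D", "description": "Postoperative flattest keratometry, 2.4-mm zone"},
    {"name": "postop_steep_k_24", "type": "float", "required": false, "units": "D", "description": "Postoperative steepest keratometry, 2.4-mm zone"},
    {"name": "postop_steep_axis_24", "type": "float", "required": false, "units": "deg", "description": "Postoperative steep-meridian axis, 2.4-mm zone"},
    {"name": "postop_flat_k_33", "type": "float", "required": false, "units": "D", "description": "Postoperative flattest keratometry, 3.3-mm zone"},
    {"name": "postop_steep_k_33", "type": "float", "required": false, "units": "D", "description": "Postoperative steepest keratometry, 3.3-mm zone"},
    {"name": "postop_steep_axis_33", "type": "float", "required": false, "units": "deg", "description": "Postoperative steep-meridian axis, 3.3-mm zone"},
    {"name": "ref_sphere", "type": "float", "required": true, "units": "D", "description": "Postoperative manifest refraction sphere (spectacle plane)"},
    {"name": "ref_cylinder", "type": "float", "required": true, "units": "D", "description": "Postoperative manifest refraction cylinder (convention per dialect)"},
    {"name": "ref_axis", "type": "float", "required": true, "units": "deg", "description": "Postoperative manifest refraction cylinder axis"},
    {"name": "corneal_irregularity", "type": "float", "required": false, "description": "Scheimpflug corneal irregularity index (dimensionless)"},
    {"name": "bcva_decimal", "type": "float", "required": false, "description": "Postoperative best-corrected visual acuity, decimal notation"},
    {"name": "prior_refractive_surgery", "type": "bool (0/1)", "required": false, "description": "History of corneal refractive or other astigmatism-altering surgery"},
    {"name": "complication", "type": "bool (0/1)", "required": false, "description": "Intra/postoperative complication risking IOL decentration or malposition"},
    {"name": "corneal_opacity", "type": "bool (0/1)", "required": false, "description": "Corneal opacity"}
  ],
  "notes": "Keratometry columns come in per-zone blocks of three; a zone block may be omitted entirely, but at least one complete block (preop and postop) is required and every eye in a file must carry the same zones."
}
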