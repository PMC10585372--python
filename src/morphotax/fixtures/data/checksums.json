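{
 "nereididae_genera.json": "144f3e5afb22b839f47054261a27a719915c0a03a5896a3c7dd3a305940589a6",
 "nereididae_key.json": "f72156a4716626fc886a531c359e95823f626a7056894a3107b1366bba3c7524",
 "nereididae_diagnoses.json": "27cec4f38d57f275dbce5e637cb23f374aeee602c6a2d1cc9eda9d03ba1691ef"
}
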