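{
  "title": "planmat run report",
  "required": {
    "stage": "string",
    "version": "string",
    "python": "string",
    "seed": "integer_or_null",
    "config": "object",
    "inputs": "object",
    "summary": "object"
  }
}
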