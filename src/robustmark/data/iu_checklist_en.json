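{
  "task": "cookie_theft_picture",
  "language": "en",
  "items": [
    ["wash"],
    ["dry"],
    ["steal"],
    ["overflow"],
    ["try", "help"],
    ["fall"],
    ["wobble"],
    ["hang"],
    ["ignore"],
    ["reach"],
    ["ask"],
    ["laugh"],
    ["stand"]
  ]
}
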