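bone density decreased
bone formation decreased
bone loss
bone marrow oedema syndrome
osteopenia
osteoporosis
osteoporosis postmenopausal
osteoporotic fracture
resorption bone increased
senile osteoporosis
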