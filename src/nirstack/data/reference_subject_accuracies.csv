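subject,fft,stack,lstm,bilstm,cnn
Sub 1,93.85,90.46,83.08,79.23,92.31
Sub 2,93.85,88.92,79.23,84.62,90.38
Sub 3,86.15,84.06,77.69,76.92,85.38
Sub 4,89.23,85.38,80.0,80.77,89.23
Sub 5,90.77,90.77,78.46,87.69,92.46
Sub 6,93.85,88.62,73.85,86.92,93.85
Sub 7,85.38,86.15,77.69,78.46,83.08
Sub 8,85.38,83.54,80.77,76.92,77.69
Sub 9,96.92,93.08,83.08,91.54,87.69
Sub 10,89.23,85.15,75.38,82.31,86.92
Sub 11,89.23,87.69,83.08,85.38,88.77
Sub 12,91.54,88.38,80.0,90.0,72.31
Sub 13,89.23,89.23,82.31,80.77,94.62
Sub 14,85.38,83.08,71.54,73.85,77.69
Sub 15,85.38,84.0,80.0,80.0,84.62
Sub 16,93.08,85.31,82.31,84.62,78.46
Sub 17,93.85,90.0,80.0,86.15,89.23
Sub 18,87.69,82.31,81.54,72.31,86.92
Sub 19,94.62,93.08,84.62,70.77,68.46
Sub 20,87.69,80.85,74.62,88.46,83.08
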