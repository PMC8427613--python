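name: hg19
chromosomes:
  "1": {length: 249250621, centromere: 125000000}
  "2": {length: 243199373, centromere: 93300000}
  "3": {length: 198022430, centromere: 91000000}
  "4": {length: 191154276, centromere: 50400000}
  "5": {length: 180915260, centromere: 48400000}
  "6": {length: 171115067, centromere: 61000000}
  "7": {length: 159138663, centromere: 59900000}
  "8": {length: 146364022, centromere: 45600000}
  "9": {length: 141213431, centromere: 49000000}
  "10": {length: 135534747, centromere: 40200000}
  "11": {length: 135006516, centromere: 53700000}
  "12": {length: 133851895, centromere: 35800000}
  "13": {length: 115169878, centromere: 17900000}
  "14": {length: 107349540, centromere: 17600000}
  "15": {length: 102531392, centromere: 19000000}
  "16": {length: 90354753, centromere: 36600000}
  "17": {length: 81195210, centromere: 24000000}
  "18": {length: 78077248, centromere: 17200000}
  "19": {length: 59128983, centromere: 26500000}
  "20": {length: 63025520, centromere: 27500000}
  "21": {length: 48129895, centromere: 13200000}
  "22": {length: 51304566, centromere: 14700000}
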